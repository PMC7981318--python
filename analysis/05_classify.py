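#!/usr/bin/env python
"""Step 5: ACMG/AMP classification of the bundled PRPF31 variant panel.

Assembles criteria per variant (frequency evidence against the disease-model
cutoff, in-silico annotations where available, assay-derived PS3/BS3 at the
control-capped strength) and applies the published combining rules.
Writes results/classifications.csv.
"""

from pathlib import Path

import pandas as pd

from ciliascreen import acmg, datasets, rescuecall

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

N_BENIGN_CONTROLS = 3
N_PATHOGENIC_CONTROLS = 3


def main() -> None:
    cutoff = acmg.maf_cutoff()
    print(f"disease-model MAF cutoff: {acmg.round_sig(cutoff, 2):.2g}")
    table = datasets.load_variant_table()
    records = datasets.variant_records(table)
    calls = datasets.fixture_functional_calls(table)
    rows = []
    for rec in records:
        fc = None
        reported = calls.get(rec.protein_change)
        if reported is not None and reported is not rescuecall.Call.INDETERMINATE:
            fc = rescuecall.FunctionalCall(
                construct_id=rec.protein_change,
                mean_z=float("nan"),
                call=reported,
                strength=rescuecall.evidence_strength(
                    N_BENIGN_CONTROLS, N_PATHOGENIC_CONTROLS, reported
                ),
            )
        crits = acmg.assemble_criteria(rec, fc, cutoff=cutoff)
        cls = acmg.classify(crits)
        rows.append(
            {
                "gene": rec.gene,
                "cdna_change": rec.cdna_change,
                "protein_change": rec.protein_change,
                "criteria": ";".join(
                    f"{c.code.value}:{c.strength.value}" for c in crits.applied
                ),
                "tier": cls.tier.value,
                "rationale": " | ".join(cls.rationale),
            }
        )
    out = RESULTS / "classifications.csv"
    RESULTS.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(out, index=False)
    print(df[["protein_change", "criteria", "tier"]].to_string(index=False))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
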