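#!/usr/bin/env python
"""Step 6: QC arithmetic for the edited clone's junction reads and dosage.

Inputs are the junction-spanning read counts per RNA fraction and replicate
(editable below), plus a mutant/wild-type transcript-abundance pair. Writes
results/editqc.csv with insertion percentages (half-up, 1 d.p.), the dosage
ratio, and the allele-bias note when both fractions are low.
"""

from pathlib import Path

import pandas as pd

from ciliascreen import editqc

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

# junction-spanning read counts: (sample, fraction, n_ref, n_ins)
READ_COUNTS = [
    ("clone_rep1", "nuclear", 46, 2),
    ("clone_rep2", "nuclear", 92, 11),
    ("clone_rep3", "nuclear", 48, 0),
    ("clone_rep1", "cytoplasmic", 70, 2),
    ("clone_rep2", "cytoplasmic", 61, 4),
    ("clone_rep3", "cytoplasmic", 53, 2),
]

# transcript abundance in the edited clone vs the unedited line (arbitrary
# FPKM-like units); a ratio near 0.5 is consistent with haploinsufficiency
DOSAGE_MUT, DOSAGE_WT = 5.2, 10.4


def main() -> None:
    rows = []
    for sample, fraction, n_ref, n_ins in READ_COUNTS:
        rows.append(
            {
                "sample": sample,
                "fraction": fraction,
                "n_ref": n_ref,
                "n_ins": n_ins,
                "insertion_pct": editqc.insertion_fraction(n_ref=n_ref, n_ins=n_ins),
            }
        )
    df = pd.DataFrame(rows)

    by_fraction = df.groupby("fraction")["insertion_pct"].mean()
    note = editqc.allele_bias_note(
        by_fraction.get("nuclear", 100.0), by_fraction.get("cytoplasmic", 100.0)
    )
    ratio = editqc.dosage_ratio(DOSAGE_MUT, DOSAGE_WT)

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "editqc.csv"
    df.to_csv(out, index=False)
    print(df.to_string(index=False))
    print(
        f"dosage ratio {ratio.ratio:.2f} "
        f"(haploinsufficiency-consistent: {ratio.haploinsufficiency_consistent})"
    )
    if note:
        print(f"note: {note}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
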