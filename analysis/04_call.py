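#!/usr/bin/env python
"""Step 4: BS3/PS3 functional-evidence calls from the replicate summary.

The assay's decision band comes from the validation controls on the same
plates: lower cutoff = mean z of the pathogenic controls, upper cutoff =
mean z of the benign controls. Constructs strictly below the lower cutoff
earn PS3, strictly above the upper cutoff BS3, anything else indeterminate;
with three controls per class the evidence strength is capped at supporting.
Writes results/calls.csv.
"""

from pathlib import Path

import pandas as pd

from ciliascreen import rescuecall

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    summary = pd.read_csv(RESULTS / "summary.csv")
    summary = summary[summary["metric"] == "pct_single_cilium"]
    by_role = {role: grp for role, grp in summary.groupby("role")}
    thresholds = rescuecall.derive_thresholds(
        benign_z=list(by_role["benign_control"]["mean_z"]),
        pathogenic_z=list(by_role["pathogenic_control"]["mean_z"]),
    )
    print(
        f"thresholds from validation controls: "
        f"lower={thresholds.lower:.3f} upper={thresholds.upper:.3f}"
    )
    rows = []
    for _, r in summary.iterrows():
        fc = rescuecall.call_variant(
            float(r["mean_z"]), thresholds, construct_id=r["construct"]
        )
        rows.append(
            {
                "construct": fc.construct_id,
                "role": r["role"],
                "mean_z": fc.mean_z,
                "sem_z": r["sem_z"],
                "n_plates": r["n_plates"],
                "lower": thresholds.lower,
                "upper": thresholds.upper,
                "call": fc.call.value,
                "strength": fc.strength.value,
            }
        )
    out = RESULTS / "calls.csv"
    calls = pd.DataFrame(rows)
    calls.to_csv(out, index=False)
    print(calls.to_string(index=False))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
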