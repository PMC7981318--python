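#!/usr/bin/env python
"""Step 3: robust z scores per construct and plate, aggregated across
replicates.

Each construct's plate value (median of its three wells' per-well medians)
is normalized against the mock-transfected negative control:
z = (x - median(mock)) / MAD(mock). Replicates combine as mean +/- SEM.
Writes results/scores.csv (per plate) and results/summary.csv (aggregated).
"""

from pathlib import Path

import pandas as pd

from ciliascreen import platestats
from ciliascreen.plate import PlateLayout

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "plates"
RESULTS = ROOT / "results"


def main() -> None:
    fields = pd.read_csv(RESULTS / "fields.csv")
    score_tables = []
    for plate_id, plate_fields in fields.groupby("plate"):
        layout = PlateLayout.from_yaml(SCRATCH / plate_id / "layout.yaml")
        score_tables.append(platestats.score_plate(plate_fields, layout))
    scores = pd.concat(score_tables, ignore_index=True)
    scores.to_csv(RESULTS / "scores.csv", index=False)
    summary = platestats.summarize_plates(score_tables)
    summary.to_csv(RESULTS / "summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"wrote {RESULTS / 'scores.csv'} and {RESULTS / 'summary.csv'}")


if __name__ == "__main__":
    main()
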