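#!/usr/bin/env python
"""Step 2: segment and measure every rendered plate into one fields table.

Reads the TIFF pairs written by 01_simulate.py and writes per-field counts
(nuclei, whole cells, cilia, % whole cells with a single cilium) to
results/fields.csv, with the analysis configuration logged alongside.
"""

import json
from pathlib import Path

import pandas as pd

from ciliascreen import hci

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "plates"
RESULTS = ROOT / "results"


def main() -> None:
    config = hci.HCIConfig()
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "hci_config.json").write_text(
        json.dumps(config.as_dict(), indent=2) + "\n"
    )
    tables = []
    for plate_dir in sorted(SCRATCH.iterdir()):
        if not plate_dir.is_dir():
            continue
        plate_id = plate_dir.name
        fields = hci.analyze_image_dir(plate_dir, plate_id, config)
        print(f"{plate_id}: {len(fields)} fields analyzed")
        tables.append(fields)
    out = RESULTS / "fields.csv"
    pd.concat(tables, ignore_index=True).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
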