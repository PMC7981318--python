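#!/usr/bin/env python
"""Step 1: render three replicate rescue-panel plates (TIFFs + ground truth).

Images and per-cell truth tables are large, so they go to scratch/plates/;
downstream steps read from there. Each plate gets its own seed, making every
biological replicate an independent simulation of the same panel.
"""

from pathlib import Path

from ciliascreen import synthgen
from ciliascreen.plate import build_layout

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "plates"
PLATE_SEEDS = (1, 2, 3)


def main() -> None:
    assignments, effects = synthgen.rescue_panel()
    for seed in PLATE_SEEDS:
        plate_id = f"plate{seed:02d}"
        outdir = SCRATCH / plate_id
        outdir.mkdir(parents=True, exist_ok=True)
        layout = build_layout(assignments, plate_id=plate_id)
        truth = synthgen.render_plate_to_dir(layout, effects, outdir, seed=seed)
        print(f"{plate_id}: {len(truth)} ground-truth cells -> {outdir}")


if __name__ == "__main__":
    main()
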