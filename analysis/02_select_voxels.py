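"""Reliability-based voxel selection.

Correlates each voxel's group-average 15-condition profile across the two
stimulus halves and keeps voxels with split-half reliability r > 0.3.
Writes the per-voxel reliability map and selection mask to
results/02_reliability.tsv and prints the survival fraction.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from scenescale import select, synth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "dataset")
    parser.add_argument("--threshold", type=float, default=select.DEFAULT_RELIABILITY_CUTOFF)
    args = parser.parse_args()

    dataset = synth.load_dataset(args.data_dir)
    reliability = select.splithalf_reliability(dataset)
    mask = select.select_voxels(reliability, args.threshold)

    table = pd.DataFrame(
        {
            "voxel": np.arange(dataset.n_voxels),
            "family": dataset.voxel_labels,
            "r": reliability.r,
            "selected": mask.astype(int),
        }
    )
    (ROOT / "results").mkdir(exist_ok=True)
    table.to_csv(ROOT / "results" / "02_reliability.tsv", sep="\t", index=False)

    pct = 100.0 * mask.sum() / mask.size
    print(f"selected {mask.sum()}/{mask.size} voxels ({pct:.1f}%) at r > {args.threshold}")
    print(table.groupby("family")["r"].mean().rename("mean_r").to_string())


if __name__ == "__main__":
    main()
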