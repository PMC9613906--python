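"""Population-level representational geometry of the selected voxels.

Computes the 15 x 15 correlation-distance RDM over the selected voxel
patterns, a 2-D classical MDS embedding, and the PCA eigenspectrum with
3-D PC scores.  Writes results/06_rdm.tsv, 06_mds2d.tsv,
06_eigenspectrum.tsv and 06_pc_scores.tsv, and saves diagnostic figures
under scratch/figures/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from scenescale import geometry, select, synth, tuning

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "dataset")
    args = parser.parse_args()

    dataset = synth.load_dataset(args.data_dir)
    mask = select.select_voxels(select.splithalf_reliability(dataset))
    matrix = tuning.group_average(dataset, mask)

    rdm = geometry.condition_rdm(matrix)
    mds = geometry.classical_mds(rdm, dims=2)
    spectrum = geometry.pca_eigenspectrum(matrix)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    np.savetxt(results / "06_rdm.tsv", rdm, delimiter="\t")
    pd.DataFrame(
        {"condition": np.arange(1, 16), "mds1": mds[:, 0], "mds2": mds[:, 1]}
    ).to_csv(results / "06_mds2d.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "component": np.arange(1, spectrum.proportions.size + 1),
            "variance_proportion": spectrum.proportions,
        }
    ).to_csv(results / "06_eigenspectrum.tsv", sep="\t", index=False)
    pd.DataFrame(
        spectrum.scores, columns=["pc1", "pc2", "pc3"]
    ).assign(condition=np.arange(1, 16)).to_csv(
        results / "06_pc_scores.tsv", sep="\t", index=False
    )

    figures = ROOT / "scratch" / "figures"
    figures.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    im = axes[0].imshow(rdm, cmap="viridis", origin="lower")
    axes[0].set_title("condition RDM (1 - Pearson)")
    fig.colorbar(im, ax=axes[0], shrink=0.8)
    sc = axes[1].scatter(mds[:, 0], mds[:, 1], c=np.arange(1, 16), cmap="coolwarm")
    axes[1].set_title("classical MDS (2-D)")
    fig.colorbar(sc, ax=axes[1], shrink=0.8, label="condition")
    axes[2].plot(np.arange(1, 16), spectrum.proportions[:15], "o-")
    axes[2].set_title("PCA eigenspectrum")
    axes[2].set_xlabel("principal component")
    fig.tight_layout()
    fig.savefig(figures / "06_geometry.png", dpi=120)

    pc1, pc2 = spectrum.proportions[:2] * 100
    print(f"PC1 explains {pc1:.1f}% of variance, PC2 {pc2:.1f}%")
    order = geometry.rdm_condition_order_along_axis(rdm)
    print(f"condition order along MDS axis 1: |Spearman| = {order:.3f}")


if __name__ == "__main__":
    main()
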