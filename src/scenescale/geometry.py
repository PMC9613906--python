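"""Population-level representational geometry.

The distributed voxel pattern for each of the 15 conditions is compared to
every other via 1 - Pearson correlation, giving a 15 x 15 representational
dissimilarity matrix (RDM).  The RDM is visualized with classical
(Torgerson) multidimensional scaling, and the dimensionality of the
population code is summarized by the PCA eigenspectrum of the
condition x voxel matrix (per-voxel centering across conditions, no
variance scaling — so a population of pure linear ramps is exactly rank 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def condition_rdm(matrix: np.ndarray) -> np.ndarray:
    """Correlation-distance RDM between condition rows.

    ``matrix`` is conditions x voxels; ``d[i, j] = 1 - Pearson(row_i,
    row_j)`` across voxels.  Symmetric, zero diagonal, entries in [0, 2].
    A zero-variance condition pattern makes the correlation undefined and is
    a hard error naming the condition.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("need a conditions x voxels matrix with >= 2 voxels")
    sd = matrix.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance pattern for condition(s) {[int(i) + 1 for i in bad]}; "
            "correlation distance undefined"
        )
    d = 1.0 - np.corrcoef(matrix)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def _check_rdm(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def classical_mds(d: np.ndarray, dims: int = 2, strict_dims: bool = True) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a dissimilarity matrix.

    Double-centers ``-0.5 * d**2``, eigendecomposes, and builds coordinates
    from the top ``dims`` positive eigenpairs; negative eigenvalues (non-
    Euclidean structure) are truncated.  If fewer than ``dims`` positive
    eigenvalues exist the embedding is reduced, with a warning when
    ``strict_dims``.  The configuration is centered at the origin; axes are
    defined only up to sign/rotation, so comparisons should use pairwise
    distances, not raw coordinates.
    """
    d = _check_rdm(d)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-12 * max(eigvals.max(initial=0.0), 1.0))
    n_pos = int((eigvals > tol).sum())
    use = min(dims, n_pos)
    if use < dims and strict_dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; embedding reduced to {use} dims",
            RuntimeWarning,
            stacklevel=2,
        )
    if use == 0:
        return np.zeros((n, min(dims, 1)))
    coords = eigvecs[:, :use] * np.sqrt(eigvals[:use])
    return coords - coords.mean(axis=0)


@dataclass(frozen=True)
class Eigenspectrum:
    """Proportion of variance per principal component, plus condition scores
    on the first three PCs (for the 3-D population-trajectory plot)."""

    proportions: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        p = self.proportions
        if np.any(p < -1e-12):
            raise ValueError("variance proportions must be nonnegative")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("variance proportions must sum to 1")
        if np.any(np.diff(p) > 1e-12):
            raise ValueError("variance proportions must be nonincreasing")


def pca_eigenspectrum(matrix: np.ndarray) -> Eigenspectrum:
    """PCA of the condition x voxel matrix.

    Each voxel column is centered across conditions (no scaling); the
    proportions are eigenvalues of the resulting covariance over its trace,
    and the scores place each condition in the space of the first (up to) 3
    principal components.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 conditions and >= 2 voxels")
    centered = matrix - matrix.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("matrix has zero variance after centering")
    n_scores = min(3, s.size)
    scores = u[:, :n_scores] * s[:n_scores]
    return Eigenspectrum(proportions=var / total, scores=scores)


def rdm_condition_order_along_axis(d: np.ndarray) -> float:
    """Spearman rank correlation between condition index and the first MDS
    axis — 1.0 when the embedding lays the continuum out monotonically."""
    from scipy.stats import spearmanr

    coords = classical_mds(d, dims=1, strict_dims=False)
    rho = spearmanr(np.arange(d.shape[0]), coords[:, 0]).statistic
    return float(abs(rho))
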