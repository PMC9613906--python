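"""Response profile clustering (RPC).

Voxels are grouped by the similarity of their normalized 15-condition
response profiles using k-means with correlation distance
``d(x, y) = 1 - Pearson(x, y)`` (10 replicates, 500 max iterations by
default).  Profiles are first transformed to zero mean and unit length; on
that sphere the correlation distance equals half the squared Euclidean
distance, and the inertia-optimal centroid of a cluster is the renormalized
member mean, so Lloyd iterations still descend monotonically.

The module also provides the k-selection diagnostics (mean pairwise centroid
similarity and the Calinski-Harabasz Variance Ratio Criterion over k = 2..20),
MDS-derived RGB cluster colors, and two stability analyses: agreement of the
solutions from the two stimulus halves, and agreement across random
participant splits, both scored by voxel-pair co-assignment (Hit / FA /
Miss -> Dice and d').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import geometry
from .synth import N_CONDITIONS, ResponseDataset

DEFAULT_REPLICATES = 10
DEFAULT_MAX_ITER = 500
DEFAULT_K_RANGE = range(2, 21)


def normalize_profiles(matrix: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Zero-mean, unit-length transform of each voxel column.

    Returns the normalized 15 x V' matrix with zero-variance (constant)
    columns removed, plus the list of excluded column indices.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != N_CONDITIONS:
        raise ValueError(f"expected {N_CONDITIONS} condition rows")
    centered = matrix - matrix.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    keep = norms > 0
    excluded = list(np.flatnonzero(~keep))
    if not keep.any():
        raise ValueError("all profiles are constant; nothing to normalize")
    return centered[:, keep] / norms[keep], excluded


@dataclass(frozen=True)
class ClusteringSolution:
    """One k-means solution: per-voxel cluster ids 1..k, zero-mean unit-norm
    centroid profiles (k x 15), total correlation-distance inertia, and the
    inertia trace of the winning replicate."""

    k: int
    assignment: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int
    inertia_history: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.assignment.min() < 1 or self.assignment.max() > self.k:
            raise ValueError("cluster ids must lie in 1..k")
        if self.centroids.shape != (self.k, N_CONDITIONS):
            raise ValueError("centroids must be k x 15")


def _normalize_rows(rows: np.ndarray) -> np.ndarray:
    rows = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return rows / norms


def _kpp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under correlation distance; x rows are normalized."""
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d = 1.0 - x @ centers[0]
    for j in range(1, k):
        w = np.clip(d, 0.0, None)
        total = w.sum()
        idx = rng.integers(n) if total <= 0 else rng.choice(n, p=w / total)
        centers[j] = x[idx]
        d = np.minimum(d, 1.0 - x @ centers[j])
    return centers


def _lloyd(
    x: np.ndarray, k: int, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One replicate of correlation-distance k-means on normalized rows."""
    centroids = _kpp_init(x, k, rng)
    labels = np.full(x.shape[0], -1)
    history: list[float] = []
    for _ in range(max_iter):
        sim = x @ centroids.T  # (n, k); distance = 1 - sim
        new_labels = sim.argmax(axis=1)
        dist = 1.0 - sim[np.arange(x.shape[0]), new_labels]
        # re-seed empty clusters from the globally farthest point
        for j in range(k):
            if not np.any(new_labels == j):
                far = int(dist.argmax())
                centroids[j] = x[far]
                new_labels[far] = j
                dist[far] = 0.0
        history.append(float(dist.sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = x[labels == j]
            centroids[j] = members.mean(axis=0)
        centroids = _normalize_rows(centroids)
    sim = x @ centroids.T
    labels = sim.argmax(axis=1)
    inertia = float((1.0 - sim[np.arange(x.shape[0]), labels]).sum())
    history.append(inertia)
    return labels, centroids, inertia, history


def cluster_profiles(
    matrix: np.ndarray,
    k: int,
    replicates: int = DEFAULT_REPLICATES,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
) -> ClusteringSolution:
    """Correlation-distance k-means over voxel response profiles.

    ``matrix`` is 15 x V (raw betas are fine; profiles are normalized
    internally, and constant columns are an error — mask them out first).
    The best of ``replicates`` independent runs by inertia is returned;
    identical seed means identical solution.
    """
    matrix = np.asarray(matrix, dtype=float)
    normalized, excluded = normalize_profiles(matrix)
    if excluded:
        raise ValueError(
            f"constant voxel profiles at columns {excluded}; exclude them before clustering"
        )
    x = normalized.T  # voxels as rows
    n = x.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available voxels")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float, list[float]] | None = None
    for _ in range(replicates):
        result = _lloyd(x, k, max_iter, rng)
        if best is None or result[2] < best[2]:
            best = result
    labels, centroids, inertia, history = best
    return ClusteringSolution(
        k=k,
        assignment=labels + 1,
        centroids=centroids,
        inertia=inertia,
        seed=seed,
        inertia_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# k-selection diagnostics
# ---------------------------------------------------------------------------


def variance_ratio_criterion(points: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz score: [B/(k-1)] / [W/(n-k)] with squared-Euclidean
    between- (B) and within-cluster (W) dispersion.  Perfect separation
    (W = 0) is reported as +inf."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    n = points.shape[0]
    ids = np.unique(labels)
    k = ids.size
    if k < 2 or n <= k:
        raise ValueError("need 2 <= k < n for the variance ratio criterion")
    grand = points.mean(axis=0)
    b = w = 0.0
    for cid in ids:
        members = points[labels == cid]
        center = members.mean(axis=0)
        b += members.shape[0] * float(((center - grand) ** 2).sum())
        w += float(((members - center) ** 2).sum())
    if w == 0.0:
        return np.inf
    return (b / (k - 1)) / (w / (n - k))


def mean_centroid_similarity(centroids: np.ndarray) -> float:
    """Mean pairwise Pearson correlation between cluster centroid profiles."""
    c = _normalize_rows(np.asarray(centroids, dtype=float))
    k = c.shape[0]
    if k < 2:
        raise ValueError("need at least 2 centroids")
    sims = c @ c.T
    iu = np.triu_indices(k, 1)
    return float(sims[iu].mean())


@dataclass(frozen=True)
class KScanReport:
    """Per-k diagnostics over a contiguous k range."""

    ks: np.ndarray
    centroid_similarity: np.ndarray
    vrc: np.ndarray
    solutions: tuple[ClusteringSolution, ...]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ks) != 1):
            raise ValueError("k range must be contiguous")


def scan_k(
    matrix: np.ndarray,
    k_range: range = DEFAULT_K_RANGE,
    replicates: int = DEFAULT_REPLICATES,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
) -> KScanReport:
    """Cluster at every k in ``k_range`` and report mean pairwise centroid
    similarity and the Variance Ratio Criterion (computed on the normalized
    profiles, the same space the clustering runs in)."""
    normalized, excluded = normalize_profiles(np.asarray(matrix, dtype=float))
    if excluded:
        raise ValueError(f"constant voxel profiles at columns {excluded}")
    points = normalized.T
    ks, sims, vrcs, sols = [], [], [], []
    for k in k_range:
        sol = cluster_profiles(matrix, k, replicates, max_iter, seed)
        ks.append(k)
        sims.append(mean_centroid_similarity(sol.centroids))
        vrcs.append(variance_ratio_criterion(points, sol.assignment))
        sols.append(sol)
    return KScanReport(
        ks=np.asarray(ks),
        centroid_similarity=np.asarray(sims),
        vrc=np.asarray(vrcs),
        solutions=tuple(sols),
    )


def cluster_colors(centroids: np.ndarray) -> np.ndarray:
    """RGB triplet per cluster from 3-D classical MDS on centroid
    correlation distances, each axis min-max rescaled to [0, 1] — similar
    response profiles get similar hues."""
    c = _normalize_rows(np.asarray(centroids, dtype=float))
    k = c.shape[0]
    if k < 2:
        raise ValueError("need at least 2 centroids to assign colors")
    d = 1.0 - c @ c.T
    np.fill_diagonal(d, 0.0)
    coords = geometry.classical_mds(d, dims=3, strict_dims=False)
    rgb = np.zeros((k, 3))
    rgb[:, : coords.shape[1]] = coords
    spans = rgb.max(axis=0) - rgb.min(axis=0)
    for axis in range(3):
        if spans[axis] > 0:
            rgb[:, axis] = (rgb[:, axis] - rgb[:, axis].min()) / spans[axis]
        else:
            rgb[:, axis] = 0.5
    return rgb


# ---------------------------------------------------------------------------
# Stability of the clustering solution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StabilityReport:
    """Voxel-pair co-assignment agreement between two clustering solutions.

    Over all unordered voxel pairs (self-pairs excluded): hit pairs are
    co-assigned in both solutions, miss pairs co-assigned in a only, false
    alarms co-assigned in b only.  Dice = 2*hit / (2*hit + fa + miss) on the
    pair counts — the Dice overlap of the two co-assignment pair sets, which
    is symmetric in its arguments.  The rates Hit = P(same in b | same in a)
    and FA = P(same in b | different in a) feed d' = z(Hit) - z(FA), with
    both rates clamped to [1/(2P), 1 - 1/(2P)] (P = the relevant pair count)
    so d' stays finite at Hit = 1 or FA = 0.
    """

    dice: float
    dprime: float
    hit_rate: float
    fa_rate: float
    n_same_pairs: int
    n_diff_pairs: int

    def __post_init__(self) -> None:
        if np.isfinite(self.dice) and not 0.0 <= self.dice <= 1.0 + 1e-12:
            raise ValueError("Dice must lie in [0, 1]")


def _assignment_of(solution) -> np.ndarray:
    labels = getattr(solution, "assignment", solution)
    return np.asarray(labels)


def _same_pairs(labels: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(labels.size, 1)
    return labels[iu[0]] == labels[iu[1]]


def coassignment_stability(sol_a, sol_b) -> StabilityReport:
    """Score how well one clustering's voxel-pair structure predicts
    another's.  Accepts ClusteringSolutions or raw label arrays over the
    same voxel set; self-pairs are excluded."""
    a = _assignment_of(sol_a)
    b = _assignment_of(sol_b)
    if a.shape != b.shape:
        raise ValueError("solutions cover different voxel sets")
    if a.size < 2:
        raise ValueError("need at least 2 voxels")
    same_a = _same_pairs(a)
    same_b = _same_pairs(b)
    n_same = int(same_a.sum())
    n_diff = int((~same_a).sum())
    if n_same == 0 or n_diff == 0:
        warnings.warn(
            "degenerate pair structure (all pairs same or all different in "
            "the reference solution); rates undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return StabilityReport(np.nan, np.nan, np.nan, np.nan, n_same, n_diff)
    n_hit = int(same_b[same_a].sum())
    n_fa = int(same_b[~same_a].sum())
    n_miss = n_same - n_hit
    hit = n_hit / n_same
    fa = n_fa / n_diff
    dice = 2.0 * n_hit / (2 * n_hit + n_fa + n_miss)
    hit_c = np.clip(hit, 1.0 / (2 * n_same), 1.0 - 1.0 / (2 * n_same))
    fa_c = np.clip(fa, 1.0 / (2 * n_diff), 1.0 - 1.0 / (2 * n_diff))
    dprime = float(norm.ppf(hit_c) - norm.ppf(fa_c))
    return StabilityReport(dice, dprime, hit, fa, n_same, n_diff)


def stimulus_splithalf_stability(
    dataset: ResponseDataset,
    k: int,
    mask: np.ndarray | None = None,
    replicates: int = DEFAULT_REPLICATES,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
) -> tuple[StabilityReport, ClusteringSolution, ClusteringSolution]:
    """Cluster each stimulus half's group-average matrix independently and
    score the agreement of the two solutions."""
    if dataset.config.n_splits != 2:
        raise ValueError("requires a dataset with 2 stimulus splits")
    if mask is None:
        mask = np.ones(dataset.n_voxels, dtype=bool)
    seeds = np.random.SeedSequence(seed).generate_state(2)
    sol_a = cluster_profiles(
        dataset.split_average(0)[:, mask], k, replicates, max_iter, int(seeds[0])
    )
    sol_b = cluster_profiles(
        dataset.split_average(1)[:, mask], k, replicates, max_iter, int(seeds[1])
    )
    return coassignment_stability(sol_a, sol_b), sol_a, sol_b


@dataclass(frozen=True)
class StabilityScan:
    """Participant-split stability over a range of k: per-iteration Dice and
    d' (n_iterations x n_k), with mean/sd summaries."""

    ks: np.ndarray
    dice: np.ndarray
    dprime: np.ndarray

    @property
    def dice_mean(self) -> np.ndarray:
        return self.dice.mean(axis=0)

    @property
    def dice_sd(self) -> np.ndarray:
        return self.dice.std(axis=0, ddof=1) if self.dice.shape[0] > 1 else np.zeros_like(self.dice_mean)

    @property
    def dprime_mean(self) -> np.ndarray:
        return self.dprime.mean(axis=0)

    @property
    def dprime_sd(self) -> np.ndarray:
        return self.dprime.std(axis=0, ddof=1) if self.dprime.shape[0] > 1 else np.zeros_like(self.dprime_mean)


def participant_splithalf_stability(
    dataset: ResponseDataset,
    k_range: range = DEFAULT_K_RANGE,
    n_iterations: int = 50,
    seed: int = 0,
    mask: np.ndarray | None = None,
    replicates: int = DEFAULT_REPLICATES,
    max_iter: int = DEFAULT_MAX_ITER,
) -> StabilityScan:
    """How well one half of the participants predicts the other.

    Each iteration randomly splits the participants into two groups
    (floor/ceil halves when the count is odd), clusters each group's average
    matrix at every k, and scores the co-assignment agreement; reported per
    iteration and k.
    """
    n_participants = dataset.config.n_participants
    if n_participants < 2:
        raise ValueError("need at least 2 participants to split")
    if mask is None:
        mask = np.ones(dataset.n_voxels, dtype=bool)
    rng = np.random.default_rng(seed)
    ks = np.asarray(list(k_range))
    dice = np.empty((n_iterations, ks.size))
    dprime = np.empty((n_iterations, ks.size))
    half = n_participants // 2
    for it in range(n_iterations):
        order = rng.permutation(n_participants)
        groups = (order[:half], order[half:])
        matrices = [
            dataset.betas[g].mean(axis=(0, 1))[:, mask] for g in groups
        ]
        for j, k in enumerate(ks):
            seeds = rng.integers(0, 2**31 - 1, size=2)
            sol_a = cluster_profiles(matrices[0], int(k), replicates, max_iter, int(seeds[0]))
            sol_b = cluster_profiles(matrices[1], int(k), replicates, max_iter, int(seeds[1]))
            report = coassignment_stability(sol_a, sol_b)
            dice[it, j] = report.dice
            dprime[it, j] = report.dprime
    return StabilityScan(ks=ks, dice=dice, dprime=dprime)


def crossval_cluster_profiles(
    solution: ClusteringSolution, heldout_matrix: np.ndarray
) -> tuple[np.ndarray, list[int]]:
    """Cluster response profiles on held-out data.

    Applies a clustering solution obtained from one data half to betas from
    the other: for each cluster, the mean of its member voxels' normalized
    held-out profiles (k x 15).  Clusters left with no members are returned
    as NaN rows and listed.
    """
    heldout_matrix = np.asarray(heldout_matrix, dtype=float)
    if heldout_matrix.shape[0] != N_CONDITIONS:
        raise ValueError(f"expected {N_CONDITIONS} condition rows")
    if heldout_matrix.shape[1] != solution.assignment.size:
        raise ValueError("held-out voxel set does not match the clustering solution")
    centered = heldout_matrix - heldout_matrix.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    ok = norms > 0
    normalized = np.where(ok, centered / np.where(ok, norms, 1.0), np.nan)
    profiles = np.full((solution.k, N_CONDITIONS), np.nan)
    empty: list[int] = []
    for cid in range(1, solution.k + 1):
        members = (solution.assignment == cid) & ok
        if members.any():
            profiles[cid - 1] = normalized[:, members].mean(axis=1)
        else:
            empty.append(cid)
    return profiles, empty
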