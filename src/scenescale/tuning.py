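"""Voxel-wise tuning characterization.

Two complementary views of each voxel's tuning over the 15-step continuum:

* a preference map — the condition with the highest group-average response,
  together with the margin over the runner-up (the hue/saturation pair of
  cortical preference maps); and
* a Gaussian peak fit — least-squares fit of
  ``baseline + amplitude * exp(-(c - mu)^2 / (2 sigma^2))`` with ``mu`` and
  ``sigma`` on exhaustive grids and the linear parameters solved exactly per
  grid point, which catches voxels whose preference is broad rather than
  sharply peaked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import CONDITIONS, N_CONDITIONS, ResponseDataset, TuningProfile

DEFAULT_MU_GRID = np.arange(1.0, N_CONDITIONS + 0.5, 0.5)
DEFAULT_SIGMA_GRID = np.arange(0.5, N_CONDITIONS + 0.5, 0.5)


def group_average(dataset: ResponseDataset, mask: np.ndarray | None = None) -> np.ndarray:
    """15 x |mask| group-level matrix: betas averaged over participants and
    splits, restricted to the masked voxels."""
    if mask is None:
        mask = np.ones(dataset.n_voxels, dtype=bool)
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError("mask must be boolean")
    if not mask.any():
        raise ValueError("empty voxel mask")
    return dataset.group_matrix()[:, mask]


@dataclass(frozen=True)
class PreferenceMap:
    """Per-voxel preferred condition (ordinal 1..15) and top-1 minus top-2
    response margin; ``valid`` is False for voxels with non-finite profiles."""

    preferred_condition: np.ndarray
    margin: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        ok = self.valid
        if np.any(self.margin[ok] < 0):
            raise ValueError("margins must be nonnegative")
        pc = self.preferred_condition[ok]
        if pc.size and (pc.min() < 1 or pc.max() > N_CONDITIONS):
            raise ValueError("preferred conditions must lie in 1..15")


def preference_map(matrix: np.ndarray) -> PreferenceMap:
    """Argmax condition and top-two margin per voxel column.

    Ties on the maximum break toward the lowest condition index (so a flat
    profile prefers condition 1 with margin 0).  Columns containing
    non-finite values are flagged invalid.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != N_CONDITIONS:
        raise ValueError(f"expected {N_CONDITIONS} condition rows")
    valid = np.all(np.isfinite(matrix), axis=0)
    safe = np.where(np.isfinite(matrix), matrix, -np.inf)
    preferred = safe.argmax(axis=0) + 1
    top2 = -np.partition(-safe, 1, axis=0)[:2]
    margin = top2[0] - top2[1]
    preferred = np.where(valid, preferred, 0)
    margin = np.where(valid, margin, np.nan)
    return PreferenceMap(preferred_condition=preferred, margin=margin, valid=valid)


@dataclass(frozen=True)
class GaussianFit:
    """Best grid-search Gaussian fit to one tuning profile.

    ``peak_defined`` is False when the fitted amplitude is (numerically)
    zero — a flat profile carries no peak information.
    """

    mu: float
    sigma: float
    amplitude: float
    baseline: float
    sse: float
    peak_defined: bool

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.sse < -1e-12:
            raise ValueError("sse must be >= 0")


def fit_gaussian_tuning(
    profile: TuningProfile | np.ndarray,
    sigma_grid: np.ndarray = DEFAULT_SIGMA_GRID,
    mu_grid: np.ndarray = DEFAULT_MU_GRID,
) -> GaussianFit:
    """Exhaustive-grid Gaussian fit of a 15-condition profile.

    For every (mu, sigma) grid point the basis ``g(c) = exp(-(c-mu)^2 /
    (2 sigma^2))`` is fixed and (baseline, amplitude) solve the 2-parameter
    linear least-squares problem exactly, with amplitude constrained
    nonnegative (this is a peak estimator; a trough-shaped profile falls
    back to the flat fit and is flagged peak-undefined); the returned fit is
    the global SSE minimum over the grid.  Deterministic by construction —
    there is no iterative optimizer to initialize.
    """
    y = profile.values if isinstance(profile, TuningProfile) else np.asarray(profile, float)
    if y.shape != (N_CONDITIONS,):
        raise ValueError(f"profile must have length {N_CONDITIONS}")
    mu_grid = np.asarray(mu_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if mu_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if np.any(sigma_grid <= 0):
        raise ValueError("all sigma grid values must be > 0")

    mus, sigmas = np.meshgrid(mu_grid, sigma_grid, indexing="ij")
    mus, sigmas = mus.ravel(), sigmas.ravel()
    # basis matrix, one Gaussian bump per grid point: (grid, conditions)
    g = np.exp(-((CONDITIONS[None, :] - mus[:, None]) ** 2) / (2.0 * sigmas[:, None] ** 2))

    # closed-form 2x2 normal equations per grid point for (baseline, amplitude)
    n = float(N_CONDITIONS)
    sg = g.sum(axis=1)
    sgg = (g * g).sum(axis=1)
    sy = y.sum()
    sgy = g @ y
    det = n * sgg - sg**2
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    amplitude = (n * sgy - sg * sy) / det
    # a peak fit: negative amplitudes (troughs) clamp to the boundary
    # amplitude = 0, where the optimal baseline is the profile mean
    amplitude = np.where(np.isnan(amplitude) | (amplitude < 0), 0.0, amplitude)
    baseline = (sy - amplitude * sg) / n
    resid = y[None, :] - (baseline[:, None] + amplitude[:, None] * g)
    sse = (resid**2).sum(axis=1)

    best = int(np.argmin(sse))
    amp = float(amplitude[best])
    peak_defined = abs(amp) > 1e-10 * max(1.0, float(np.abs(y).max()))
    return GaussianFit(
        mu=float(mus[best]),
        sigma=float(sigmas[best]),
        amplitude=amp,
        baseline=float(baseline[best]),
        sse=float(sse[best]),
        peak_defined=peak_defined,
    )
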