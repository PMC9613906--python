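"""Reliability-based voxel selection.

A voxel is kept when its 15-condition response profile replicates across
the two independent stimulus halves: split-half reliability is the Pearson
correlation between the group-average profile from split 1 and from split 2,
and voxels with r strictly above the cutoff (0.3 by default) survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synth import ResponseDataset

DEFAULT_RELIABILITY_CUTOFF = 0.3


@dataclass(frozen=True)
class ReliabilityMap:
    """Per-voxel split-half Pearson correlation.

    ``r`` is NaN where the correlation is undefined (a zero-variance profile
    in either split); ``defined`` flags the voxels where it exists.
    """

    r: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            if np.any(np.abs(self.r[self.defined]) > 1 + 1e-12):
                raise ValueError("|r| must be <= 1 where defined")


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between matching columns of two (conditions x voxels) arrays;
    returns (r, defined)."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    sa = np.sqrt((ac**2).sum(axis=0))
    sb = np.sqrt((bc**2).sum(axis=0))
    defined = (sa > 0) & (sb > 0)
    r = np.full(a.shape[1], np.nan)
    r[defined] = (ac[:, defined] * bc[:, defined]).sum(axis=0) / (
        sa[defined] * sb[defined]
    )
    np.clip(r, -1.0, 1.0, out=r, where=defined)
    return r, defined


def splithalf_reliability(
    dataset: ResponseDataset, per_participant: bool = False
) -> ReliabilityMap:
    """Split-half reliability per voxel.

    By default the betas are averaged over participants within each split
    first, and the two group-average 15-condition vectors are correlated
    (the group-level procedure).  With ``per_participant=True`` the
    correlation is instead computed within each participant and averaged
    across participants (voxels undefined for any participant stay
    undefined).
    """
    if dataset.config.n_splits != 2:
        raise ValueError("split-half reliability requires exactly 2 splits")
    if not per_participant:
        return ReliabilityMap(
            *_rowwise_pearson(dataset.split_average(0), dataset.split_average(1))
        )
    rs, defineds = [], []
    for p in range(dataset.config.n_participants):
        r, defined = _rowwise_pearson(dataset.betas[p, 0], dataset.betas[p, 1])
        rs.append(r)
        defineds.append(defined)
    defined = np.all(defineds, axis=0)
    r = np.where(defined, np.mean(rs, axis=0), np.nan)
    return ReliabilityMap(r=r, defined=defined)


def select_voxels(
    reliability: ReliabilityMap, threshold: float = DEFAULT_RELIABILITY_CUTOFF
) -> np.ndarray:
    """Boolean mask: voxels whose reliability is defined and strictly exceeds
    the threshold.  Ties at the cutoff are excluded; undefined correlations
    never pass."""
    with np.errstate(invalid="ignore"):
        mask = reliability.defined & (reliability.r > threshold)
    if not mask.any():
        warnings.warn(
            "no voxels pass the reliability threshold", RuntimeWarning, stacklevel=2
        )
    return mask
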