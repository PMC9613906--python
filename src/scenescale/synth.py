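"""Synthetic multi-participant voxel datasets with planted tuning structure.

The generator emulates the structure of a blocked fMRI experiment over a
15-step object-to-scene continuum: per participant, betas for 15 ordinal
conditions in each of two stimulus-split halves (environment set A vs. B,
standing in for odd/even runs).  Voxels are drawn from planted tuning
families — decreasing ramp (object-preferring), increasing ramp
(scene-preferring), an intermediate Gaussian peak, and a shallower
early-visual-like ramp — with i.i.d. Gaussian noise added per cell.
Ground-truth family labels travel with the dataset so downstream cluster
recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

N_CONDITIONS = 15
N_SPLITS = 2

#: Condition axis: ordinal indices 1..15 (close-up object .. full-scene view).
CONDITIONS = np.arange(1, N_CONDITIONS + 1, dtype=float)

PROFILE_KINDS = ("ramp_down", "ramp_up", "gaussian_peak")


class InvalidParameterError(ValueError):
    """Raised for non-finite or out-of-domain tuning parameters."""


@dataclass(frozen=True)
class TuningProfile:
    """A voxel's noiseless response over the 15 ordinal conditions."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_CONDITIONS,):
            raise InvalidParameterError(
                f"profile must have length {N_CONDITIONS}, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("profile contains non-finite values")
        object.__setattr__(self, "values", values)


def make_profile(kind: str, params: dict) -> TuningProfile:
    """Evaluate a parametric tuning profile at condition indices 1..15.

    Parameters
    ----------
    kind:
        ``"ramp_down"`` / ``"ramp_up"`` (linear: ``intercept + slope * c``)
        or ``"gaussian_peak"`` (``baseline + amplitude *
        exp(-(c - mu)**2 / (2 * sigma**2))``).  The two ramp kinds share the
        linear form; the name records the intended sign of the slope but the
        slope parameter is taken as given.
    params:
        Ramp: ``intercept``, ``slope``.  Gaussian: ``mu`` in [1, 15],
        ``sigma`` > 0, ``amplitude``, ``baseline``.
    """
    if kind not in PROFILE_KINDS:
        raise InvalidParameterError(f"unknown profile kind {kind!r}")
    for key, value in params.items():
        if not np.isfinite(value):
            raise InvalidParameterError(f"parameter {key}={value!r} is not finite")
    if kind in ("ramp_down", "ramp_up"):
        values = params["intercept"] + params["slope"] * CONDITIONS
    else:
        mu, sigma = params["mu"], params["sigma"]
        if sigma <= 0:
            raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
        if not 1 <= mu <= N_CONDITIONS:
            raise InvalidParameterError(f"mu must lie in [1, {N_CONDITIONS}], got {mu}")
        values = params["baseline"] + params["amplitude"] * np.exp(
            -((CONDITIONS - mu) ** 2) / (2.0 * sigma**2)
        )
    return TuningProfile(values)


@dataclass(frozen=True)
class ClusterSpec:
    """One planted tuning family: profile shape, parameters, voxel count."""

    kind: str
    params: dict
    n_voxels: int
    name: str = ""

    def profile(self) -> TuningProfile:
        return make_profile(self.kind, self.params)


def default_cluster_specs() -> tuple[ClusterSpec, ...]:
    """The default planted mix: opposing ramps spanning [0, 1], a Gaussian
    peak at the intermediate scale, and a shallower second increasing ramp
    mimicking early-visual tissue."""
    s = 1.0 / (N_CONDITIONS - 1)
    return (
        ClusterSpec("ramp_down", {"intercept": 1.0 + s, "slope": -s}, 100, "object_ramp"),
        ClusterSpec("ramp_up", {"intercept": -s, "slope": s}, 100, "scene_ramp"),
        ClusterSpec(
            "gaussian_peak",
            {"mu": 8.0, "sigma": 2.0, "amplitude": 1.0, "baseline": 0.0},
            100,
            "intermediate_peak",
        ),
        ClusterSpec(
            "ramp_up", {"intercept": 0.25 - 0.5 * s, "slope": 0.5 * s}, 100, "early_visual"
        ),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the study design: 12 participants, 15 conditions, two
    stimulus-split halves.  ``noise_sd`` is the standard deviation of the
    i.i.d. Gaussian noise added to every participant/split/condition/voxel
    cell, in the same response units as the planted profiles (which span a
    range of ~1).
    """

    n_participants: int = 12
    cluster_specs: Sequence[ClusterSpec] = field(default_factory=default_cluster_specs)
    noise_sd: float = 0.8
    seed: int = 0
    voxel_baseline_sd: float = 0.0
    n_conditions: int = N_CONDITIONS
    n_splits: int = N_SPLITS

    def __post_init__(self) -> None:
        if self.voxel_baseline_sd < 0:
            raise ValueError("voxel_baseline_sd must be >= 0")
        if self.n_conditions != N_CONDITIONS:
            raise ValueError(f"n_conditions is fixed at {N_CONDITIONS}")
        if self.n_splits != N_SPLITS:
            raise ValueError(f"n_splits is fixed at {N_SPLITS}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.cluster_specs:
            raise ValueError("cluster_specs must be nonempty")
        for spec in self.cluster_specs:
            if spec.n_voxels < 1:
                raise ValueError("every cluster must contain at least 1 voxel")

    @property
    def n_voxels(self) -> int:
        return sum(spec.n_voxels for spec in self.cluster_specs)


@dataclass(frozen=True)
class ResponseDataset:
    """Participant x split x condition x voxel beta estimates.

    ``betas`` has shape ``(n_participants, n_splits, 15, n_voxels)``.
    ``voxel_labels`` carries the ground-truth planted family index per voxel
    (0-based into ``config.cluster_specs``).
    """

    betas: np.ndarray
    config: GeneratorConfig
    voxel_labels: np.ndarray | None = None
    condition_axis: np.ndarray = field(default_factory=lambda: CONDITIONS.copy())

    def __post_init__(self) -> None:
        expected = (
            self.config.n_participants,
            self.config.n_splits,
            self.config.n_conditions,
            self.config.n_voxels,
        )
        if self.betas.shape != expected:
            raise ValueError(f"betas shape {self.betas.shape} != config shape {expected}")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas contain non-finite values")
        if not np.all(np.diff(self.condition_axis) > 0):
            raise ValueError("condition axis must be strictly increasing")

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[3]

    def split_average(self, split: int) -> np.ndarray:
        """Group-average matrix (15 x V) for one split: mean over participants."""
        return self.betas[:, split].mean(axis=0)

    def group_matrix(self) -> np.ndarray:
        """Group-average matrix (15 x V): mean over participants and splits."""
        return self.betas.mean(axis=(0, 1))

    def participant_matrix(self, participant: int) -> np.ndarray:
        """One participant's matrix (15 x V), averaged over the two splits."""
        return self.betas[participant].mean(axis=0)


def planted_profiles(config: GeneratorConfig) -> np.ndarray:
    """Noiseless 15 x V matrix of each voxel's planted profile."""
    columns = []
    for spec in config.cluster_specs:
        profile = spec.profile().values
        columns.append(np.tile(profile[:, None], (1, spec.n_voxels)))
    return np.concatenate(columns, axis=1)


def generate_dataset(config: GeneratorConfig) -> ResponseDataset:
    """Draw a synthetic dataset: planted profiles plus i.i.d. Gaussian noise.

    Every voxel inherits its family's noiseless profile exactly; independent
    ``N(0, noise_sd**2)`` noise is added per participant/split/condition/voxel
    cell.  ``voxel_baseline_sd > 0`` additionally gives each voxel a constant
    ``N(0, voxel_baseline_sd**2)`` offset shared across all cells — a signal
    the profile normalization downstream is supposed to remove.  The same
    config (including seed) always yields a bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    truth = planted_profiles(config)
    if config.voxel_baseline_sd > 0:
        truth = truth + rng.normal(0.0, config.voxel_baseline_sd, size=config.n_voxels)
    shape = (config.n_participants, config.n_splits, config.n_conditions, config.n_voxels)
    betas = truth[None, None] + rng.normal(0.0, config.noise_sd, size=shape)
    labels = np.concatenate(
        [np.full(spec.n_voxels, i) for i, spec in enumerate(config.cluster_specs)]
    )
    return ResponseDataset(betas=betas, config=config, voxel_labels=labels)


# ---------------------------------------------------------------------------
# On-disk form: one delimited-text matrix per (participant, split) plus a
# JSON sidecar holding the config, condition axis and ground-truth labels.
# ---------------------------------------------------------------------------


def save_dataset(dataset: ResponseDataset, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    for p in range(cfg.n_participants):
        for s in range(cfg.n_splits):
            path = directory / f"sub-{p + 1:02d}_split-{s + 1}.tsv"
            np.savetxt(path, dataset.betas[p, s], delimiter="\t")
    sidecar = {
        "n_participants": cfg.n_participants,
        "n_splits": cfg.n_splits,
        "n_conditions": cfg.n_conditions,
        "noise_sd": cfg.noise_sd,
        "voxel_baseline_sd": cfg.voxel_baseline_sd,
        "seed": cfg.seed,
        "condition_axis": dataset.condition_axis.tolist(),
        "cluster_specs": [
            {
                "kind": spec.kind,
                "params": spec.params,
                "n_voxels": spec.n_voxels,
                "name": spec.name,
            }
            for spec in cfg.cluster_specs
        ],
        "voxel_labels": (
            dataset.voxel_labels.tolist() if dataset.voxel_labels is not None else None
        ),
    }
    sidecar_path = directory / "dataset.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return sidecar_path


def load_dataset(directory: str | Path) -> ResponseDataset:
    directory = Path(directory)
    meta = json.loads((directory / "dataset.json").read_text())
    specs = tuple(
        ClusterSpec(s["kind"], s["params"], s["n_voxels"], s.get("name", ""))
        for s in meta["cluster_specs"]
    )
    config = GeneratorConfig(
        n_participants=meta["n_participants"],
        cluster_specs=specs,
        noise_sd=meta["noise_sd"],
        voxel_baseline_sd=meta.get("voxel_baseline_sd", 0.0),
        seed=meta["seed"],
    )
    betas = np.empty(
        (config.n_participants, config.n_splits, config.n_conditions, config.n_voxels)
    )
    for p in range(config.n_participants):
        for s in range(config.n_splits):
            betas[p, s] = np.loadtxt(
                directory / f"sub-{p + 1:02d}_split-{s + 1}.tsv", delimiter="\t"
            )
    labels = meta.get("voxel_labels")
    return ResponseDataset(
        betas=betas,
        config=config,
        voxel_labels=None if labels is None else np.asarray(labels),
        condition_axis=np.asarray(meta["condition_axis"], dtype=float),
    )
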