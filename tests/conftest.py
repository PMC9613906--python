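import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scenescale import synth

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

S = 1.0 / (synth.N_CONDITIONS - 1)

THREE_CLUSTER_SPECS = (
    synth.ClusterSpec("ramp_down", {"intercept": 1.0 + S, "slope": -S}, 60, "object_ramp"),
    synth.ClusterSpec("ramp_up", {"intercept": -S, "slope": S}, 60, "scene_ramp"),
    synth.ClusterSpec(
        "gaussian_peak",
        {"mu": 8.0, "sigma": 2.0, "amplitude": 1.0, "baseline": 0.0},
        60,
        "intermediate_peak",
    ),
)


@pytest.fixture(scope="session")
def three_cluster_noiseless():
    """12 participants, 3 planted families, no measurement noise."""
    config = synth.GeneratorConfig(
        cluster_specs=THREE_CLUSTER_SPECS, noise_sd=0.0, seed=11
    )
    return synth.generate_dataset(config)


@pytest.fixture(scope="session")
def three_cluster_low_noise():
    """Same planted structure with noise at 0.1x the profile range."""
    config = synth.GeneratorConfig(
        cluster_specs=THREE_CLUSTER_SPECS, noise_sd=0.1, seed=11
    )
    return synth.generate_dataset(config)


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions (4 families, noise 0.8)."""
    return synth.generate_dataset(synth.GeneratorConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
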