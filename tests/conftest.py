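import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fecgbse import (
    SceneConfig,
    default_scene,
    generate_sources,
    mix,
    benchmark_mixing_matrix,
    whiten,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scene_config():
    return SceneConfig()


@pytest.fixture(scope="session")
def six_sources(scene_config):
    """One seeded realization of the canonical six-source scene."""
    return generate_sources(
        list(scene_config.specs), scene_config.n_samples, scene_config.fs_hz, seed=42
    )


@pytest.fixture(scope="session")
def mixed_scene(six_sources):
    """(sources, A, mixture, whitened mixture, whitening transform)."""
    A = benchmark_mixing_matrix()
    x = mix(six_sources, A)
    x_white, transform = whiten(x)
    return six_sources, A, x, x_white, transform


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
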