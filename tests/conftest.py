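import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import zebraldt as z

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> z.GeneratorConfig:
    return z.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def quiet_config() -> z.GeneratorConfig:
    """Noise-free configuration: records equal the generator means exactly."""
    return z.GeneratorConfig(seed=7, between_larva_cv=0.0, within_larva_noise_sd=0.0)


@pytest.fixture(scope="session")
def null_config() -> z.GeneratorConfig:
    """No exposure effect: control and exposed share one generating process."""
    return z.GeneratorConfig(seed=7, effect=z.EffectSpec(multiplier=1.0))


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return z.generate_cohort(default_config)


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    return z.assemble_matrix(default_cohort)


@pytest.fixture(scope="session")
def small_null_matrix():
    """Tiny uniform-noise two-class matrix for fast harness checks."""
    return z.generate_null_matrix(n_per_class=15, n_features=30, seed=11)


@pytest.fixture()
def separable_matrix():
    """Two point clouds separated far beyond their noise scale."""
    rng = np.random.default_rng(3)
    n, p = 20, 12
    a = rng.normal(0.0, 1.0, size=(n, p))
    b = rng.normal(25.0, 1.0, size=(n, p))
    return z.FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(2 * n)],
        labels=np.array(["control"] * n + ["exposed"] * n),
        features=np.vstack([a, b]),
    )
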