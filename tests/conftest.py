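import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hrvmix import GaussianMixture, sample_mixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_component_truth():
    """Well-separated reference mixture used throughout the recovery tests."""
    return GaussianMixture.from_arrays(
        [0.5, 0.3, 0.2], [60.0, 90.0, 120.0], [16.0, 25.0, 36.0]
    )


@pytest.fixture(scope="session")
def three_component_sample(three_component_truth):
    values, assignments = sample_mixture(three_component_truth, 10_000, seed=7)
    return values, assignments
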