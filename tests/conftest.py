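import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient cohort with all default effects on."""
    from pdackit.simulate import CohortConfig, simulate_cohort

    return simulate_cohort(CohortConfig(n_patients=40, seed=11))
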