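import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from eaamix.simulate import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized draw from the default generator, shared across tests."""
    cohort, truth = generate_cohort(SyntheticSpec(seed=11), n=400)
    return cohort, truth


@pytest.fixture(scope="session")
def big_cohort():
    """Large draw for calibration checks (n=10,000, fixed seed)."""
    cohort, truth = generate_cohort(SyntheticSpec(seed=1), n=10_000)
    return cohort, truth
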