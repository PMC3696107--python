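import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meningioma_subgroups import SimConfig, default_peak_library, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """One default-configuration cohort shared across tests (fixed seed)."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def peak_library():
    return default_peak_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
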