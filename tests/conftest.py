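import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def extended_conc():
    """Extended substrate series (M), triplicate."""
    return np.repeat([2e-6, 1e-5, 5e-5, 2.5e-4, 1.25e-3], 3)


@pytest.fixture(scope="session")
def extended_replicates():
    return np.tile([1, 2, 3], 5)
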