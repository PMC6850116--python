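import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def reference_cohort():
    from ddmosaic import load_reference_cohort

    return load_reference_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
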