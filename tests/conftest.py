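import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bayesadc.neuromass import simulate, tune_defaults
from bayesadc.policy import default_swift_params

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=25,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dd_params():
    return tune_defaults("DD")


@pytest.fixture(scope="session")
def naive_params():
    return tune_defaults("naive")


@pytest.fixture(scope="session")
def swift_params():
    return default_swift_params(1000.0)


@pytest.fixture(scope="session")
def dd_trace_60s(dd_params):
    """Unstimulated DD trace shared by the spectral and DSP tests."""
    return simulate(dd_params, 60.0, seed=0)
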