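import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcchannel import (
    SystemParameters,
    derive_transport,
    modified_params,
    plug_descriptor,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return SystemParameters()


@pytest.fixture(scope="session")
def derived(default_params):
    return derive_transport(default_params)


@pytest.fixture(scope="session")
def plug(default_params, derived):
    return plug_descriptor(default_params, derived)


@pytest.fixture(scope="session")
def tc(default_params, derived, plug):
    return modified_params(plug.c_avg, default_params, derived.k_T_star)


@pytest.fixture(scope="session")
def default_time_grid(plug):
    return np.linspace(0.0, 1.5 * plug.t_d, 4001)
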