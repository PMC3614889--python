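import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import luxswitch as lx
from luxswitch import ode

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params01():
    """lux01 at desk-scale population size (density as in the full system)."""
    return lx.build_parameter_set({"N": 8}, "lux01")


@pytest.fixture(scope="session")
def params02():
    return lx.build_parameter_set({"N": 8}, "lux02")


@pytest.fixture(scope="session")
def gmax01(params01):
    return ode.gfp_max(params01)


@pytest.fixture(scope="session")
def gmax02(params02):
    return ode.gfp_max(params02)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
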