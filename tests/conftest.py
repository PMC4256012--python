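import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from laborleisure import leisure_utility as lu
from laborleisure import smdp_core as sc


@pytest.fixture(scope="session")
def default_task():
    """Canonical task: R_I=10 utility units, price 5 s, tau_max 100 s."""
    return sc.TaskSpec(R_I=10.0, P=5.0)


@pytest.fixture(scope="session")
def linear_u():
    return lu.linear(1.0)


@pytest.fixture(scope="session")
def log1p_u():
    return lu.log1p(5.0)


@pytest.fixture(scope="session")
def log_u():
    return lu.log(5.0)


@pytest.fixture(scope="session")
def solved_linear(default_task, linear_u):
    return sc.solve(default_task, linear_u)


@pytest.fixture(scope="session")
def solved_log(default_task, log_u):
    return sc.solve(default_task, log_u)
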