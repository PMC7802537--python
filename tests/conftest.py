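import pytest
from hypothesis import HealthCheck, settings

from toastbake import BakeConfig, load_parameters, solve_bake

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def control_params():
    return load_parameters("control")


@pytest.fixture(scope="session")
def guar_params():
    return load_parameters("guar")


@pytest.fixture(scope="session")
def bake_ctl_190(control_params):
    """Default-configuration control bake at 190 C, shared across tests."""
    return solve_bake(BakeConfig(params=control_params, T_oven=463.15))


@pytest.fixture(scope="session")
def bake_guar_190(guar_params):
    return solve_bake(BakeConfig(params=guar_params, T_oven=463.15))
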