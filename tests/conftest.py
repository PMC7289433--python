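import pytest

from sdbass import SimConfig, build_base_model, integrate


@pytest.fixture(scope="session")
def base_config():
    return SimConfig()


@pytest.fixture(scope="session")
def base_model():
    return build_base_model()


@pytest.fixture(scope="session")
def base_trajectory(base_model, base_config):
    """The published base run: 1998-2048, dt=0.125, RK4."""
    return integrate(base_model, base_config)
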