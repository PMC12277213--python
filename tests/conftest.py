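import logging

import pytest

from berryflux import SimulationConfig, default_parameters, simulate


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_result(default_config):
    """The packaged 80-day synthetic-season run, shared across tests."""
    return simulate(default_config)


@pytest.fixture(autouse=True)
def _quiet_clamp_warnings():
    logger = logging.getLogger("berryflux")
    level = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(level)
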