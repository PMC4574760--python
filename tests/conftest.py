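import pytest

import myokinetics as mk


@pytest.fixture(scope="session")
def config():
    """The shipped calibrated configuration."""
    return mk.default_config()


@pytest.fixture(scope="session")
def dynamic_run(config):
    """Reference 10%-strain run over the 21-day experiment."""
    return mk.simulate(config.with_epsilon(0.10).with_horizon(21.0))


@pytest.fixture(scope="session")
def static_run(config):
    """Reference static (0% strain) run over the 21-day experiment."""
    return mk.simulate(config.with_epsilon(0.0).with_horizon(21.0))
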