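import pytest

from mgdb import ModelConfig, fit_access_curve
from mgdb.fixtures import generate_fixtures


@pytest.fixture(scope="session")
def curve():
    """Access curve calibrated once per session to the default stepped table."""
    return fit_access_curve()


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def fixture_tables():
    return generate_fixtures(n_countries=50, seed=42)
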