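import numpy as np
import pytest

from pollugrid.config import SyntheticConfig
from pollugrid.synthetic import generate_firm_panel


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def demo_panel(default_config):
    """Small firm panel (~3,000 firm-years) shared across read-only tests."""
    return generate_firm_panel(default_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
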