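import numpy as np
import pytest

from morphrsa.design import DesignConfig, generate_block_design
from morphrsa.features import make_feature_bank


@pytest.fixture(scope="session")
def design_config():
    return DesignConfig()


@pytest.fixture(scope="session")
def block(design_config):
    return generate_block_design(design_config, seed=11)


@pytest.fixture(scope="session")
def bank():
    return make_feature_bank(n_identities=4, dim=128, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
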