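import warnings

import numpy as np
import pytest

from povmsm.derive import build_analysis_table, derive_poverty
from povmsm.simulate import generate_panel, scenario

warnings.filterwarnings("ignore", message="dropping collinear")


def prepare_table(cfg):
    """generate -> derive poverty -> lagged analysis table."""
    return build_analysis_table(derive_poverty(generate_panel(cfg)))


@pytest.fixture(scope="session")
def default_config():
    return scenario("default", 4000, n_waves=5, seed=20_2509)


@pytest.fixture(scope="session")
def default_table(default_config):
    return prepare_table(default_config)


@pytest.fixture(scope="session")
def default_weights(default_table):
    from povmsm.weights import compute_stabilized_weights

    return compute_stabilized_weights(default_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
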