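import numpy as np
import pytest

from hgtscan.model import GTRGammaParams
from hgtscan.simulate import Scenario, panel_15, species_tree_15


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def panel15():
    return panel_15()


@pytest.fixture(scope="session")
def tree15():
    return species_tree_15()


@pytest.fixture(scope="session")
def sim_params():
    """The generator's default substitution model."""
    return Scenario().params


@pytest.fixture(scope="session")
def jc_params():
    return GTRGammaParams.jc(4, alpha=1.0)
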