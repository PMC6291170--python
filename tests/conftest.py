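import numpy as np
import pytest

from alternans.ionic_models import luo_rudy_1991
from alternans.synthetic_data import minimal_pde_cell


@pytest.fixture(scope="session")
def lr91():
    """Default detailed myocyte: slowed Na recovery, control conductance."""
    return luo_rudy_1991()


@pytest.fixture(scope="session")
def fk_steep():
    return minimal_pde_cell("steep")


@pytest.fixture(scope="session")
def fk_flat():
    return minimal_pde_cell("flat")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
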