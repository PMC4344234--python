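import numpy as np
import pytest

from cyclepbm import build_grids, load_preset
from cyclepbm.kinetics import SubstrateState


@pytest.fixture(scope="session")
def nominal():
    return load_preset("table2_nominal")


@pytest.fixture(scope="session")
def estimated():
    return load_preset("table2_estimated")


@pytest.fixture(scope="session")
def small(nominal):
    """Nominal parameters on a coarse grid for fast end-to-end tests."""
    return nominal.replace(nE=40, nDNA=10, nB=40)


@pytest.fixture(scope="session")
def tiny(nominal):
    return nominal.replace(nE=20, nDNA=5, nB=20)


@pytest.fixture(scope="session")
def grid_small(small):
    return build_grids(small)


@pytest.fixture
def rich_substrates():
    """Substrate state far from limitation (all limiting factors near 1)."""
    return SubstrateState(Glu=200.0, Glc=500.0, Lac=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
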