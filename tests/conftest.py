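import numpy as np
import pytest

from sifsvd import (
    RetrievalConfig,
    SolarModel,
    SpectralGrid,
    compute_svs,
    make_training_set,
)


@pytest.fixture(scope="session")
def grid():
    return SpectralGrid.regular()


@pytest.fixture(scope="session")
def solar():
    return SolarModel()


@pytest.fixture(scope="session")
def training_matrix(grid, solar):
    return make_training_set(grid, solar, 400, seed=101)


@pytest.fixture(scope="session")
def basis(grid, solar, training_matrix):
    return compute_svs(training_matrix, grid, 8)


@pytest.fixture(scope="session")
def big_basis(grid, solar):
    """Basis from a training archive large enough for low-bias retrievals."""
    return compute_svs(make_training_set(grid, solar, 2000, seed=11), grid, 8)


@pytest.fixture(scope="session")
def huge_basis(grid, solar):
    """Basis from a training archive at the scale of the reference archive."""
    return compute_svs(make_training_set(grid, solar, 6000, seed=11), grid, 8)


@pytest.fixture
def config():
    return RetrievalConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
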