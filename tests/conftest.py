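import numpy as np
import pytest

from colorgrain import fixtures as fx


@pytest.fixture(scope="session")
def grid():
    return fx.default_grid()


@pytest.fixture(scope="session")
def d65(grid):
    return fx.d65(grid)


@pytest.fixture(scope="session")
def cmfs(grid):
    return fx.cie1931_cmfs(grid)


@pytest.fixture(scope="session")
def basis(grid):
    return fx.standard_basis(grid)[1]


@pytest.fixture(scope="session")
def tripartition(grid):
    return fx.standard_basis(grid)[0]


@pytest.fixture(scope="session")
def rgb(grid):
    return fx.standard_rgb_cmfs(grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
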