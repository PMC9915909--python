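import numpy as np
import pytest

import ecolag as e


@pytest.fixture(scope="session")
def grid_regions():
    """4x4 grid of unit squares, the study-shaped default geometry."""
    return e.generate_regions(e.SyntheticConfig())


@pytest.fixture(scope="session")
def queen_w(grid_regions):
    return e.queen_contiguity(grid_regions)


@pytest.fixture(scope="session")
def row_w(queen_w):
    return e.row_standardize(queen_w)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (seed 0)."""
    return e.generate_study(e.SyntheticConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
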