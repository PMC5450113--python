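import numpy as np
import pytest

import ddtv_pat as dp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixtures():
    """Small deterministic phantoms/sinograms/fields shared by unit tests."""
    return dp.make_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_problem():
    """A 16x16 grid with 8 detectors and its triangular system matrix."""
    grid = dp.make_grid(16, 16, 16.0)
    geom = dp.circular_scan(8, 14.0)
    sampling = dp.default_sampling(grid, geom)
    W = dp.build_weight_matrix(geom, grid, sampling)
    return grid, geom, sampling, W
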