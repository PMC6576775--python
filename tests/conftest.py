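import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from multiscale_occupancy import (
    CovariateTable,
    DetectionArray,
    default_method_map,
    pool_histories,
    simulate_covariates,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def mmap():
    return default_method_map()


@pytest.fixture
def small_array():
    """Two sites x five cameras x four occasions with a missing visit."""
    obs = np.zeros((2, 5, 4), dtype=np.int8)
    obs[0, 0, 0] = 1  # site 1: camera A detects on day 1
    obs[0, 1, 2] = 1  # site 1: camera B detects on day 3
    obs[1, :, 1] = -1  # site 2: whole array missing on day 2
    return DetectionArray(["s1", "s2"], ["A", "B", "C", "D", "E"], [4, 4], obs)


def empty_covariates(site_ids):
    return CovariateTable(pd.DataFrame(index=pd.Index(site_ids, name="site")))


@pytest.fixture
def cov_factory():
    return empty_covariates


@pytest.fixture
def sim_covariates(mmap):
    cov = simulate_covariates(48, mmap, seed=9)
    return cov
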