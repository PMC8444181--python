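import numpy as np
import pandas as pd
import pytest

from siginfo.synthetic import SyntheticConfig

#: Package-wide seed for every randomised test.
SEED = 1


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def default_config():
    """The study-scale generator configuration (defaults, test seed)."""
    return SyntheticConfig(seed=SEED)


@pytest.fixture
def small_config():
    """A fast configuration for plumbing tests (distributions unchanged)."""
    return SyntheticConfig(seed=SEED, n_cells=600)


def bivariate_gaussian(rho: float, n: int, seed: int = SEED):
    """Correlated standard-normal pair used as the MI oracle's input."""
    g = np.random.default_rng(seed)
    cov = [[1.0, rho], [rho, 1.0]]
    xy = g.multivariate_normal([0.0, 0.0], cov, size=n)
    return xy[:, 0], xy[:, 1]


@pytest.fixture
def toy_events():
    """A small hand-built event table."""
    n = 10
    return pd.DataFrame(
        {
            "cell_index": range(n),
            "stat3": np.linspace(50, 500, n),
            "pstat3": np.linspace(5, 50, n),
            "genotype": "wt",
            "dose_ng_ml": 10.0,
            "time_min": 15,
            "replicate": 1,
        }
    )
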