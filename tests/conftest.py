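import logging
import warnings

import numpy as np
import pytest

from pyjaatha import LocusConfig, SearchSettings, build_named_model, default_partition

logging.getLogger("msprime").setLevel(logging.WARNING)
logging.getLogger("pyjaatha.search").setLevel(logging.WARNING)
warnings.filterwarnings("ignore", message=".*did not converge.*")


class LinearPoissonSimulator:
    """Toy simulator: counts are Poisson with log-linear means in the
    log-parameters.  Stands in for the coalescent pipeline in search tests."""

    count_scale = 1.0

    def __init__(self, coef: np.ndarray):
        self.coef = np.asarray(coef, dtype=float)  # (n_stats, 1 + n_params)

    def mean(self, point):
        return np.exp(self.coef[:, 0] + self.coef[:, 1:] @ np.asarray(point))

    def __call__(self, point, rng):
        return rng.poisson(self.mean(point))


@pytest.fixture
def toy_2p_simulator():
    coef = np.array([
        [3.0, 1.0, 0.0],
        [3.0, 0.0, 1.0],
        [2.0, -0.5, 0.5],
        [2.5, 0.8, -0.4],
    ])
    return LinearPoissonSimulator(coef)


@pytest.fixture
def toy_2p_model():
    model = build_named_model("Constant")
    return model.with_fixed(q=1.0, m=0.05)  # free: theta, tau


@pytest.fixture
def micro_settings():
    """Smallest settings that still exercise every search phase."""
    return SearchSettings(k=2, s_ini=4, s_main=4, s_final=4, n_rp=2, n_b=2,
                          t_max=3, t_stop=2, epsilon=0.5, include_corners=False,
                          r=0.5)


@pytest.fixture
def small_locus_config():
    return LocusConfig(n_loc=10, y1=6, y2=6, seq_length_bp=500, rho=0.0,
                       outgroup_factor=2.0)


@pytest.fixture
def small_partition():
    return default_partition(6, 6)
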