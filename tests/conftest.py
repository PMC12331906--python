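import numpy as np
import pytest

from mdspectra.ir import DipoleTrajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_trajectory(rng):
    """1,000-step pseudo-random dipole trajectory at 2.5 fs."""
    return DipoleTrajectory(dt_fs=2.5, dipoles=rng.normal(size=(1000, 3)))


def direct_autocorrelation(dipoles: np.ndarray, max_lag: int, detrend: bool = True):
    """Brute-force O(N^2) ACF oracle: unbiased per-lag, summed over components."""
    mu = dipoles - dipoles.mean(axis=0) if detrend else dipoles
    M = mu.shape[0]
    out = np.empty(max_lag)
    for lag in range(max_lag):
        out[lag] = np.sum(mu[: M - lag] * mu[lag:]) / (M - lag)
    return out
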