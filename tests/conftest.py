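import numpy as np
import pytest

from stancestrength.cohort import CohortGenConfig, TraceGenConfig
from stancestrength.preprocess import ForceTrace, PreprocessConfig


def brute_force_window_max(x, win, step=1):
    """Exhaustive sliding-window maximum mean: the independent oracle.

    Loops over every window start and averages the slice directly; first
    occurrence wins ties via strict comparison.
    """
    x = np.asarray(x, dtype=float)
    best = -np.inf
    best_i = 0
    for i in range(0, len(x) - win + 1, step):
        m = float(np.mean(x[i : i + win]))
        if m > best:
            best, best_i = m, i
    return best, best_i


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_cfg():
    return PreprocessConfig()


@pytest.fixture
def quiet_trace_cfg():
    """Noise-free trace settings for exact round trips."""
    return TraceGenConfig(
        seed=7, target_mvc=400.0, tremor_sd=0.0, wideband_noise_sd=0.0, spike_rate=0.0
    )


@pytest.fixture
def fast_trace_template():
    """Short trace template to keep file-based pipeline tests quick."""
    return TraceGenConfig(
        seed=0, target_mvc=1.0, lead_in=0.2, ramp_time=0.3,
        plateau_time=1.6, release_time=0.2,
    )


@pytest.fixture
def small_cohort_cfg():
    return CohortGenConfig(
        seed=3, n_per_stratum={k: 4 for k in CohortGenConfig().n_per_stratum}
    )


def constant_trace(value=100.0, fs=1400.0, seconds=3.0):
    n = int(round(fs * seconds))
    z = np.full(n, value)
    return ForceTrace(fs=fs, fx=z.copy(), fy=z.copy(), fz=np.full(n, 700.0))
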