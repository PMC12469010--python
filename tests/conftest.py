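import numpy as np
import pytest

from subband_flda import CohortSpec, SignalRecord, simulate_cohort
from subband_flda.signal_io import ASD, DEFAULT_CHANNELS_15, NORMAL


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def record(rng):
    """A 1024-sample, 4-channel record (length divisible by 2^6)."""
    return SignalRecord(
        subject_id="S01",
        class_label=NORMAL,
        fs=256.0,
        channel_labels=("FP1", "F3", "F7", "T3"),
        data=rng.standard_normal((1024, 4)),
    )


@pytest.fixture(scope="session")
def small_spec():
    """Fast cohort: 4 subjects per class, 15 channels, 1024 samples."""
    return CohortSpec(n_subjects_per_class=4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    _, records = simulate_cohort(small_spec)
    return records


def make_two_gaussians(rng, n_per_class=200, d=2, delta=(4.0, 0.0), scale=1.0):
    """Two isotropic Gaussian clouds separated along ``delta``; labels ASD/NORMAL."""
    delta = np.zeros(d) + np.pad(np.asarray(delta, dtype=float), (0, max(0, d - len(delta))))[:d]
    X0 = scale * rng.standard_normal((n_per_class, d))
    X1 = scale * rng.standard_normal((n_per_class, d)) + delta
    X = np.vstack([X0, X1])
    y = np.array([NORMAL] * n_per_class + [ASD] * n_per_class, dtype=object)
    return X, y
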