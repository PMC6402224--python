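import numpy as np
import pytest

import ufirecg as u


@pytest.fixture(scope="session")
def interval():
    return u.default_interval(360.0)


@pytest.fixture(scope="session")
def clean_record():
    """One noiseless synthetic beat with ground truth."""
    return u.generate(u.SyntheticParams(n_beats=1))


@pytest.fixture(scope="session")
def clean_beat(clean_record):
    return u.ECGSignal(clean_record.clean.samples, 360.0, "clean beat")


@pytest.fixture(scope="session")
def noisy_record_35db():
    return u.generate(u.SyntheticParams(n_beats=100, snr_db=35.0, seed=42))


def quadratic_beat(length=300, coeffs=(0.3, -0.004, 1.2e-5)):
    """Noiseless degree-2 polynomial 'beat' (no QRS; windows set by hand)."""
    n = np.arange(length, dtype=float)
    a, b, c = coeffs
    return u.ECGSignal(a + b * n + c * n * n, 360.0, "quadratic")
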