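"""Basic signal containers.

An ECG trace is a plain 1-D sample sequence in millivolts together with its
sampling frequency.  Estimators return an :class:`EstimateSeries` aligned
index-for-index with the input, carrying the per-sample horizon and shift
actually used (constant for batch filtering, varying for adaptive smoothing
and for shrunk edge windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ECGSignal:
    """A single-lead ECG sample sequence.

    Parameters
    ----------
    samples : array-like of float
        Signal amplitudes in mV.
    fs : float
        Sampling frequency in Hz (MIT-BIH records use 360 Hz).
    label : str
        Free-text record/lead identifier.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not (self.fs > 0):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or infinite values")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class EstimateSeries:
    """Estimates x^_{n|n-p} aligned with the input samples.

    ``horizons`` and ``shifts`` record the (N, p) actually applied at each
    sample, which differs from the nominal spec near the edges (shrunk
    windows) and inside adaptive ramps.  Entries may be NaN when edge
    handling is set to leave the partial-window region undefined.
    """

    estimates: np.ndarray
    fs: float
    horizons: np.ndarray = field(repr=False, default=None)
    shifts: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)

    def __len__(self) -> int:
        return self.estimates.size
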