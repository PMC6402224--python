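"""Applying UFIR gains to signals.

The batch (constant-spec) path is a single convolution over the region
where the full horizon fits inside the signal.  Near the edges the horizon
is shrunk to the largest feasible length >= l+1, with the shift clamped so
the window stays in range; alternatively the partial-window region can be
left undefined (NaN).
"""

from __future__ import annotations

import numpy as np

from .gains import GainSpec, GainVector, compute_gains
from .signal import ECGSignal, EstimateSeries


def _clamped_spec(spec: GainSpec, n: int, length: int) -> GainSpec:
    """Largest-feasible (N', p') at sample ``n`` of a signal of ``length``.

    The window [n-N'+1-p', n-p'] must lie inside [0, length-1] with
    N' >= l+1, which requires n-length+1 <= p' <= n-l.  The requested shift
    is clamped into that range and the horizon then shrunk to fit.
    """
    l = spec.degree
    if length < l + 1:
        raise ValueError(
            f"signal of length {length} cannot support degree {l} (needs >= {l + 1})"
        )
    p = int(np.clip(spec.shift, n - length + 1, n - l))
    newest = n - p  # newest sample index in the window
    horizon = min(spec.horizon, newest + 1)
    return GainSpec(degree=l, horizon=horizon, shift=p)


def estimate_at(samples: np.ndarray, n: int, spec: GainSpec, edge: str = "shrink") -> tuple[float, GainSpec]:
    """Single-sample UFIR estimate at index ``n``; returns (value, spec used)."""
    length = samples.size
    full = spec
    newest = n - spec.shift
    oldest = newest - spec.horizon + 1
    if oldest < 0 or newest > length - 1:
        if edge == "nan":
            return float("nan"), spec
        full = _clamped_spec(spec, n, length)
        newest = n - full.shift
    h = compute_gains(full).h
    window = samples[newest - full.horizon + 1 : newest + 1][::-1]
    return float(np.dot(h, window)), full


def apply_ufir_window(window: np.ndarray, gains: GainVector) -> float:
    """Inner product of the gain row with one data window.

    ``window`` must be ordered newest-first: [s_{n-p}, s_{n-1-p}, ..., s_{m-p}],
    matching the ascending-in-i storage of the gains.
    """
    window = np.asarray(window, dtype=float)
    if window.size != gains.h.size:
        raise ValueError(
            f"window length {window.size} does not match horizon {gains.h.size}"
        )
    return float(np.dot(gains.h, window))


def apply_ufir(signal: ECGSignal, spec: GainSpec, edge: str = "shrink") -> EstimateSeries:
    """Run a constant-spec UFIR estimator over a whole signal.

    Parameters
    ----------
    signal : ECGSignal
        Input samples (must be finite; length >= degree+1).
    spec : GainSpec
        Degree / horizon / shift of the estimator.
    edge : {"shrink", "nan"}
        Where the full horizon does not fit, either shrink it to the
        largest feasible length >= l+1 with the shift clamped ("shrink",
        default, keeps output length equal to input length with no padding
        artifacts) or leave those samples NaN ("nan").

    Returns
    -------
    EstimateSeries
        Same length as the input, with per-sample (N, p) bookkeeping.
    """
    s = signal.samples
    L = s.size
    l, N, p = spec.degree, spec.horizon, spec.shift
    if L < l + 1:
        raise ValueError(f"signal length {L} < degree+1 = {l + 1}")
    if edge not in ("shrink", "nan"):
        raise ValueError(f"unknown edge mode {edge!r}")

    h = compute_gains(spec).h
    est = np.full(L, np.nan)
    horizons = np.full(L, N, dtype=int)
    shifts = np.full(L, p, dtype=int)

    # full-window region: window [n-N+1-p, n-p] inside [0, L-1]
    y = np.convolve(s, h, mode="full")  # y[k] = sum_a h[a] s[k-a]
    n_lo = max(0, N - 1 + p)
    n_hi = min(L - 1, L - 1 + p)
    if n_lo <= n_hi:
        est[n_lo : n_hi + 1] = y[n_lo - p : n_hi + 1 - p]

    for n in list(range(0, min(n_lo, L))) + list(range(max(n_hi + 1, 0), L)):
        val, used = estimate_at(s, n, spec, edge=edge)
        est[n] = val
        horizons[n] = used.horizon
        shifts[n] = used.shift

    return EstimateSeries(estimates=est, fs=signal.fs, horizons=horizons, shifts=shifts)
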