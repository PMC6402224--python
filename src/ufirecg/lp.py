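"""Standard linear-predictor comparator.

One-step linear prediction lambda^(n) = sum_{i=1..q} delta_i lambda(n-i)
with coefficients from the correlation method: biased (1/L) autocorrelation
estimates plugged into the Yule-Walker normal equations, solved with the
Levinson-type Toeplitz solver.  Order q = 2 is the conventional choice for
ECG work.  The residual eps(n) = lambda(n) - lambda^(n) is the fraction of
the signal the predictor cannot explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import lfilter

from .signal import ECGSignal, EstimateSeries


@dataclass
class LPModel:
    """Fitted linear predictor of order q."""

    order: int
    coefficients: np.ndarray
    training_span: tuple[int, int]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite predictor coefficients")


@dataclass
class LPPrediction:
    """One-step predictions with the residual series alongside.

    The first q samples have no full history; they are NaN in both the
    estimates and the residuals.
    """

    estimates: EstimateSeries
    residuals: np.ndarray


def fit_lp(signal: ECGSignal, order: int = 2, span: tuple[int, int] | None = None) -> LPModel:
    """Fit predictor coefficients by the correlation method.

    Biased autocorrelations r_k = (1/L) sum_n x_n x_{n-k} over the training
    span (the whole record by default) enter the Yule-Walker system
    R delta = r, with R the q x q symmetric Toeplitz matrix of r_0..r_{q-1}.
    The biased estimator keeps R positive semidefinite.
    """
    a, b = span if span is not None else (0, len(signal))
    x = signal.samples[a:b]
    L = x.size
    if L <= 2 * order:
        raise ValueError(f"training span of {L} samples too short for order {order}")
    r = np.array([np.dot(x[k:], x[: L - k]) / L for k in range(order + 1)])
    if r[0] == 0:
        raise ValueError("zero-power training span: autocorrelation system is singular")
    try:
        delta = solve_toeplitz(r[:order], r[1 : order + 1])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises rarely here
        raise ValueError(f"singular autocorrelation system: {exc}") from exc
    return LPModel(order=order, coefficients=delta, training_span=(a, b))


def predict_lp(signal: ECGSignal, model: LPModel) -> LPPrediction:
    """One-step predictions and residuals over a whole signal."""
    x = signal.samples
    q = model.order
    if x.size <= q:
        raise ValueError(f"signal of {x.size} samples too short for order {q}")
    est = lfilter(np.concatenate(([0.0], model.coefficients)), [1.0], x)
    est[:q] = np.nan
    res = x - est
    series = EstimateSeries(
        estimates=est,
        fs=signal.fs,
        horizons=np.full(x.size, q, dtype=int),
        shifts=np.ones(x.size, dtype=int),
    )
    return LPPrediction(estimates=series, residuals=res)
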