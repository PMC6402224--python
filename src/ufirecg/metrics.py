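"""Evaluation metrics and the method comparison harness.

RMSE against a known clean signal, output-SNR, Tukey boxplot statistics
(linear-interpolation quartiles, whiskers at 1.5 x IQR), and a helper that
runs the four estimators under comparison — the adaptive-horizon UFIR
smoother, the UFIR filter (p = 0), the UFIR one-step predictor (p = +1)
and the order-2 linear predictor — over one synthetic record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .denoise import denoise_record
from .filtering import apply_ufir
from .gains import GainSpec
from .lp import fit_lp, predict_lp
from .signal import ECGSignal
from .simulate import SyntheticRecord

METHODS = ("adaptive_smoother", "ufir_filter", "ufir_predictor", "linear_predictor")


def rmse(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Root mean squared difference; NaNs in the estimate are excluded."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError(f"length mismatch: {estimate.shape} vs {truth.shape}")
    mask = np.isfinite(estimate)
    if not mask.any():
        raise ValueError("no finite estimates to compare")
    return float(np.sqrt(np.mean((estimate[mask] - truth[mask]) ** 2)))


def output_snr_db(estimate: np.ndarray, clean: np.ndarray) -> float:
    """10 log10 of mean-removed clean power over estimation-error power."""
    err = rmse(estimate, clean) ** 2
    return 10.0 * np.log10(np.var(clean) / err)


@dataclass
class BoxplotStats:
    """Tukey five-number summary of an error sample."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_outliers: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def boxplot_stats(errors) -> BoxplotStats:
    """Median, quartiles, 1.5 x IQR whiskers and outlier count."""
    x = np.asarray(errors, dtype=float)
    if x.size == 0:
        raise ValueError("empty error sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n_outliers=int(np.sum((x < lo_fence) | (x > hi_fence))),
    )


def run_methods(
    record: SyntheticRecord,
    n_opt: int = 21,
    degree: int = 2,
    interval: int | None = None,
    lp_order: int = 2,
) -> dict[str, np.ndarray]:
    """Full-record estimates from all four methods on the noisy signal."""
    noisy = record.noisy
    _, stitched = denoise_record(
        noisy, record.beat_bounds, n_opt=n_opt, degree=degree, interval=interval
    )
    out = {"adaptive_smoother": stitched.estimates}
    out["ufir_filter"] = apply_ufir(noisy, GainSpec(degree, n_opt, 0)).estimates
    out["ufir_predictor"] = apply_ufir(noisy, GainSpec(degree, n_opt, 1)).estimates
    model = fit_lp(noisy, order=lp_order)
    out["linear_predictor"] = predict_lp(noisy, model).estimates.estimates
    return out


def method_rmse_table(
    record: SyntheticRecord,
    n_opt: int = 21,
    degree: int = 2,
    interval: int | None = None,
) -> dict[str, float]:
    """Per-method RMSE against the clean ground truth."""
    estimates = run_methods(record, n_opt=n_opt, degree=degree, interval=interval)
    clean = record.clean.samples
    return {name: rmse(est, clean) for name, est in estimates.items()}
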