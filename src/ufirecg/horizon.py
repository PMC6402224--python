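"""Optimal and adaptive averaging-horizon selection.

A long horizon N_opt gives the best denoising on the slowly varying parts
of a heartbeat (P/T waves, baseline) but biases the fast QRS excursion,
which needs the minimal horizon N_min = l+1 (exact polynomial tracking).
N_opt is not observable directly because the clean signal is unknown; it is
estimated from the mean square value (MSV) of the measurement residual
s_n - x^_n, averaged over many beats as a function of N.  The MSV curve is
smoothed with a low-degree polynomial fit, and the horizon at which its
derivative with respect to N is smallest (the knee where further widening
stops paying) yields the estimate; one index step is then added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gains import GainSpec, central_shift
from .signal import ECGSignal


@dataclass
class BeatWindows:
    """QRS protection window of one heartbeat.

    ``q_int``/``s_int`` bound the adaptation window placed symmetrically
    around the R peak; ``q``/``s`` are the detected Q and S troughs inside
    it; ``t_end`` is the last index of the beat.
    """

    q_int: int
    q: int
    r: int
    s: int
    s_int: int
    t_end: int
    interval: int
    q_at_boundary: bool = False
    s_at_boundary: bool = False

    def __post_init__(self) -> None:
        # troughs may sit on the window boundary (monotone segment, flagged)
        if not (0 <= self.q_int <= self.q < self.r < self.s <= self.s_int <= self.t_end):
            raise ValueError(
                "inconsistent beat windows: require 0 <= q_int <= q < r < s "
                f"<= s_int <= t_end, got {self}"
            )


@dataclass
class MSVCurve:
    """Mean-square residual versus horizon, with its polynomial smoothing fit."""

    n_grid: np.ndarray
    v_avg: np.ndarray
    v_fit: np.ndarray
    derivative: np.ndarray
    fit_coeffs: np.ndarray = field(repr=False, default=None)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "N": self.n_grid,
                "V_avg": self.v_avg,
                "V_fit": self.v_fit,
                "derivative": self.derivative,
            }
        )


@dataclass
class HorizonProfile:
    """Per-sample horizon lengths over one beat.

    The profile equals ``n_opt`` away from the QRS complex, ``n_min`` on
    the closed interval [Q, S], and ramps between the two with one-step
    increments, so consecutive samples never differ by more than 1.
    """

    n_apt: np.ndarray
    n_opt: int
    n_min: int

    def __post_init__(self) -> None:
        self.n_apt = np.asarray(self.n_apt, dtype=int)


def default_interval(fs: float, degree: int = 2, n_opt_guess: int = 21) -> int:
    """Adaptation-window width: two full ramps plus a nominal QRS width.

    The QRS complex of a normal beat spans roughly 0.10 s; the window must
    also host the down- and up-ramps between n_opt and n_min = degree+1.
    """
    qrs_samples = int(round(0.10 * fs))
    return 2 * (n_opt_guess - (degree + 1)) + qrs_samples


def detect_qrs_window(beat: ECGSignal, interval: int) -> BeatWindows:
    """Locate the R peak and the Q/S troughs inside a centred window.

    R is the global maximum (earliest index on ties); the window bounds are
    q_int = R - interval//2 and s_int = R + interval//2, clamped into the
    beat; Q is the argmin on [q_int, R) and S the argmin on (R, s_int].
    A trough found at a window boundary (monotone segment) is flagged.
    """
    x = beat.samples
    L = x.size
    if interval < 4:
        raise ValueError(f"interval {interval} too small to host Q and S")
    if L < 5:
        raise ValueError(f"beat of {L} samples is too short to host the window")
    r = int(np.argmax(x))
    if np.ptp(x) == 0:
        raise ValueError("no dominant R: beat is flat")
    half = interval // 2
    q_int = max(0, r - half)
    s_int = min(L - 1, r + half)
    if q_int >= r or s_int <= r:
        raise ValueError(
            f"window [{q_int}, {s_int}] around R={r} leaves no room for Q/S troughs"
        )
    q = q_int + int(np.argmin(x[q_int:r]))
    s = r + 1 + int(np.argmin(x[r + 1 : s_int + 1]))
    return BeatWindows(
        q_int=q_int,
        q=q,
        r=r,
        s=s,
        s_int=s_int,
        t_end=L - 1,
        interval=interval,
        q_at_boundary=(q == q_int),
        s_at_boundary=(s == s_int),
    )


def three_part_estimate(
    beat: ECGSignal, windows: BeatWindows, degree: int, horizon: int, shift: int | None = None
) -> np.ndarray:
    """Concatenated estimate with horizon N outside [q_int, s_int] and N_min inside.

    Used for the MSV study: the long horizon is applied to the slow parts
    before q_int and after s_int, while the QRS protection window
    [q_int, s_int] is estimated with N_min = degree+1 so that the fast
    excursion does not inflate the residual with bias.
    """
    from .filtering import apply_ufir

    if shift is None:
        shift = central_shift(horizon)
    n_min = degree + 1
    est_long = apply_ufir(beat, GainSpec(degree, horizon, shift)).estimates
    est_min = apply_ufir(beat, GainSpec(degree, n_min, central_shift(n_min))).estimates
    out = est_long.copy()
    out[windows.q_int : windows.s_int + 1] = est_min[windows.q_int : windows.s_int + 1]
    return out


def residual_msv(
    beat: ECGSignal, windows: BeatWindows, degree: int, horizon: int, shift: int | None = None
) -> float:
    """Mean squared measurement residual of the three-part estimate."""
    if horizon < degree + 1:
        raise ValueError(f"horizon {horizon} < degree+1 = {degree + 1}")
    est = three_part_estimate(beat, windows, degree, horizon, shift)
    return float(np.mean((beat.samples - est) ** 2))


def estimate_nopt(
    beats: list[ECGSignal],
    degree: int = 2,
    shift: int | None = None,
    interval: int | None = None,
    n_grid: np.ndarray | None = None,
    fit_degree: int = 4,
) -> tuple[int, MSVCurve]:
    """Estimate the optimal horizon from the averaged MSV curve.

    The per-beat MSV is averaged over beats and smoothed with a low-degree
    polynomial fit in N; the analytic derivative of the fit is minimised
    over the grid and the estimate is the grid value at the minimiser plus
    one index step.  Ties break toward smaller N.

    ``fit_degree`` defaults to 4: the MSV curve decays like the 1/N noise
    term before the squared bias takes over, and a quartic is the lowest
    degree whose derivative can hold an interior minimum between those two
    regimes (a cubic's derivative is minimised at its single inflection,
    which systematically overshoots the knee); ``fit_degree=3`` recovers
    the plain cubic reading.

    Returns
    -------
    (n_opt, curve) : (int, MSVCurve)
    """
    if not beats:
        raise ValueError("need at least one beat")
    if interval is None:
        interval = default_interval(beats[0].fs, degree)
    if n_grid is None:
        n_grid = np.arange(degree + 1, 52, 2)
    n_grid = np.asarray(n_grid, dtype=int)
    if n_grid.size < fit_degree + 1:
        raise ValueError(
            f"degree-{fit_degree} fit needs at least {fit_degree + 1} horizon grid points"
        )
    if np.any(np.diff(n_grid) <= 0) or n_grid[0] < degree + 1:
        raise ValueError("n_grid must be ascending with minimum >= degree+1")

    v = np.zeros(n_grid.size)
    for beat in beats:
        w = detect_qrs_window(beat, interval)
        for k, N in enumerate(n_grid):
            v[k] += residual_msv(beat, w, degree, int(N), shift)
    v /= len(beats)

    coeffs = np.polyfit(n_grid, v, fit_degree)
    v_fit = np.polyval(coeffs, n_grid)
    dcoeffs = np.polyder(coeffs)
    deriv = np.polyval(dcoeffs, n_grid)
    # earliest grid point within numerical-tie tolerance of the minimum,
    # so a flat (zero-residual) curve resolves to the smallest horizon
    dmin = float(deriv.min())
    atol = 1e-12 * max(1.0, abs(dmin))
    k = int(np.nonzero(deriv <= dmin + atol)[0][0])
    n_opt = int(n_grid[k]) + 1
    curve = MSVCurve(
        n_grid=n_grid, v_avg=v, v_fit=v_fit, derivative=deriv, fit_coeffs=coeffs
    )
    return n_opt, curve


def build_profile(
    windows: BeatWindows, n_opt: int, n_min: int, beat_length: int
) -> HorizonProfile:
    """Per-sample adaptive horizon over one beat.

    The horizon equals ``n_min`` on the closed QRS interval [Q, S] and
    grows by one per sample of distance from that interval, clamped at
    ``n_opt``.  When the adaptation window is at least as wide as the
    ramp, this reproduces the five-part layout exactly: N_opt before
    q_int and after s_int, one-step ramps on [q_int, Q) and (S, s_int];
    with a narrower window the ramp simply starts earlier so that the
    one-step property is never violated.
    """
    if n_opt < n_min:
        raise ValueError(f"n_opt={n_opt} must be >= n_min={n_min}")
    if beat_length <= windows.t_end:
        raise ValueError(
            f"beat_length {beat_length} inconsistent with windows (t_end={windows.t_end})"
        )
    n = np.arange(beat_length)
    dist = np.where(n < windows.q, windows.q - n, np.where(n > windows.s, n - windows.s, 0))
    n_apt = np.minimum(n_opt, n_min + dist)
    return HorizonProfile(n_apt=n_apt, n_opt=n_opt, n_min=n_min)
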