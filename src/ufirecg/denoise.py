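"""Adaptive-horizon UFIR denoising of heartbeats.

Five parts of a beat are treated differently: the slow outer parts are
smoothed with the optimal horizon N_opt, the QRS core [Q, S] with the
minimal horizon N_min = l+1 (which, with a centred shift, reproduces the
raw samples exactly and so introduces no bias on the fast excursion), and
one-step ramps bridge the two inside the adaptation window.  The shift is
re-centred at every ramp step, p = -floor((N-1)/2), so the window stays
central while N changes by one per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filtering import apply_ufir, estimate_at
from .gains import GainSpec, central_shift
from .horizon import BeatWindows, HorizonProfile, build_profile, detect_qrs_window, estimate_nopt
from .signal import ECGSignal, EstimateSeries


@dataclass
class DenoisedBeat:
    """Adaptive-horizon estimate of one heartbeat."""

    estimates: EstimateSeries
    profile: HorizonProfile
    windows: BeatWindows
    parts: tuple[tuple[int, int], ...]  # five half-open segment ranges

    @property
    def samples(self) -> np.ndarray:
        return self.estimates.estimates


def denoise_beat(
    beat: ECGSignal,
    windows: BeatWindows,
    n_opt: int,
    degree: int = 2,
    p_mode: str | int = "central",
) -> DenoisedBeat:
    """Denoise one heartbeat with the five-part adaptive-horizon smoother.

    Parameters
    ----------
    beat : ECGSignal
        One heartbeat with a dominant R maximum.
    windows : BeatWindows
        QRS protection window (see :func:`detect_qrs_window`).
    n_opt : int
        Optimal horizon for the slow parts; must be >= degree+1.
    degree : int
        Polynomial degree l of the smoother (default 2).
    p_mode : "central" or int
        "central" re-centres the shift for every instantaneous horizon;
        an integer fixes the shift (the horizon still adapts).
    """
    n_min = degree + 1
    if n_opt < n_min:
        raise ValueError(f"n_opt={n_opt} < n_min={n_min}")
    L = len(beat)
    profile = build_profile(windows, n_opt, n_min, L)

    def shift_for(N: int) -> int:
        return central_shift(N) if p_mode == "central" else int(p_mode)

    base_spec = GainSpec(degree, n_opt, shift_for(n_opt))
    series = apply_ufir(beat, base_spec)
    est = series.estimates
    horizons = series.horizons
    shifts = series.shifts

    for n in np.nonzero(profile.n_apt < n_opt)[0]:
        N = int(profile.n_apt[n])
        spec = GainSpec(degree, N, shift_for(N))
        val, used = estimate_at(beat.samples, int(n), spec)
        est[n] = val
        horizons[n] = used.horizon
        shifts[n] = used.shift

    w = windows
    parts = (
        (0, w.q_int),
        (w.q_int, w.q),
        (w.q, w.s + 1),
        (w.s + 1, w.s_int + 1),
        (w.s_int + 1, L),
    )
    out = EstimateSeries(estimates=est, fs=beat.fs, horizons=horizons, shifts=shifts)
    return DenoisedBeat(estimates=out, profile=profile, windows=w, parts=parts)


def denoise_record(
    record: ECGSignal,
    beat_boundaries: list[tuple[int, int]],
    n_opt: int | None = None,
    degree: int = 2,
    interval: int | None = None,
    p_mode: str | int = "central",
) -> tuple[list[DenoisedBeat], EstimateSeries]:
    """Denoise a record beat by beat with a shared optimal horizon.

    ``beat_boundaries`` are half-open [start, end) ranges that must be
    non-overlapping and ascending.  If ``n_opt`` is None it is estimated
    from the beats themselves.  Returns the per-beat results plus the
    stitched full-record estimate (beat-local estimates used verbatim;
    samples not covered by any beat pass through unchanged).
    """
    from .horizon import default_interval

    if interval is None:
        interval = default_interval(record.fs, degree)
    prev_end = 0
    for a, b in beat_boundaries:
        if a < prev_end or b <= a or b > len(record):
            raise ValueError(f"invalid/overlapping beat boundary ({a}, {b})")
        prev_end = b

    beats = [
        ECGSignal(record.samples[a:b], record.fs, f"{record.label}[{a}:{b}]")
        for a, b in beat_boundaries
    ]
    if n_opt is None:
        if not beats:
            raise ValueError("cannot estimate n_opt from an empty boundary list")
        n_opt, _ = estimate_nopt(beats, degree=degree, interval=interval)

    results: list[DenoisedBeat] = []
    stitched = record.samples.copy()
    horizons = np.zeros(len(record), dtype=int)
    shifts = np.zeros(len(record), dtype=int)
    for (a, b), beat in zip(beat_boundaries, beats):
        w = detect_qrs_window(beat, interval)
        db = denoise_beat(beat, w, n_opt, degree=degree, p_mode=p_mode)
        results.append(db)
        stitched[a:b] = db.samples
        horizons[a:b] = db.estimates.horizons
        shifts[a:b] = db.estimates.shifts
    full = EstimateSeries(estimates=stitched, fs=record.fs, horizons=horizons, shifts=shifts)
    return results, full
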