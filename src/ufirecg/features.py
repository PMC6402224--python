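"""Morphological feature extraction from a denoised heartbeat.

The pipeline locates the R peak and the Q/S troughs, suppresses the QRS
complex with a linear bridge to expose the P and T waves, finds their
peaks, then estimates wave onsets and offsets from extrema of the first
difference in a section adjacent to each wave peak.  Amplitudes are
reported relative to the baseline (the value at the P-wave offset, taken
as the isoelectric reference), durations in seconds, and the ST slope as
the angle between a unit temporal step and the vertical at the sample
following S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .denoise import DenoisedBeat
from .signal import ECGSignal


@dataclass
class FiducialSet:
    """Landmark indices (samples) and values (mV) of one heartbeat."""

    r_index: int
    r_value: float
    q_index: int
    q_value: float
    s_index: int
    s_value: float
    p_index: int | None = None
    p_value: float | None = None
    t_index: int | None = None
    t_value: float | None = None
    p_onset_index: int | None = None
    p_offset_index: int | None = None
    t_onset_index: int | None = None
    t_offset_index: int | None = None
    p_onset_value: float | None = None
    p_offset_value: float | None = None
    t_onset_value: float | None = None
    t_offset_value: float | None = None
    s_star_index: int | None = None
    s_star_value: float | None = None
    baseline: float | None = None


@dataclass
class BeatFeatures:
    """Amplitudes (mV, relative to baseline), durations (s) and ST angle (deg)."""

    p_amp: float
    qrs_amp: float
    t_amp: float
    p_dur: float
    qrs_dur: float
    t_dur: float
    st_angle_deg: float
    fiducials: FiducialSet


def locate_r_q_s(samples: np.ndarray, interval: int) -> FiducialSet:
    """R as global maximum, Q/S as troughs inside the centred window.

    Ties in maxima/minima break to the earliest index.  A flat beat has no
    dominant R and raises.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty beat")
    if np.ptp(x) == 0:
        raise ValueError("no dominant R: beat is flat")
    r = int(np.argmax(x))
    half = interval // 2
    q_lo = max(0, r - half)
    s_hi = min(x.size - 1, r + half)
    if q_lo >= r or s_hi <= r:
        raise ValueError(f"QRS window around R={r} falls outside the beat")
    q = q_lo + int(np.argmin(x[q_lo:r]))
    s = r + 1 + int(np.argmin(x[r + 1 : s_hi + 1]))
    return FiducialSet(
        r_index=r, r_value=float(x[r]),
        q_index=q, q_value=float(x[q]),
        s_index=s, s_value=float(x[s]),
    )


def suppress_qrs(samples: np.ndarray, q_index: int, s_index: int) -> np.ndarray:
    """Replace [Q, S] with a linear bridge between the values at Q and S.

    Leaves the P and T maxima intact so they can be located by plain
    argmax on either side of the bridge.
    """
    x = np.asarray(samples, dtype=float).copy()
    if s_index < q_index:
        raise ValueError("s_index before q_index")
    if s_index > q_index:
        x[q_index : s_index + 1] = np.linspace(
            x[q_index], x[s_index], s_index - q_index + 1
        )
    return x


def locate_wave_bounds(
    signal: np.ndarray,
    peak_index: int,
    segment_start: int,
    segment_end: int,
    section_fraction: float = 0.5,
) -> tuple[int, int]:
    """Onset/offset of a wave from first-difference extrema.

    The pre-peak segment [segment_start, peak] contributes the onset as
    the argmax of the first difference within its trailing section (the
    part adjacent to the peak); the post-peak segment [peak, segment_end]
    contributes the offset as the argmin of the first difference within
    its leading section.  Section width is ``section_fraction`` of the
    segment length.  Returned indices are absolute.
    """
    x = np.asarray(signal, dtype=float)
    if not (segment_start <= peak_index <= segment_end):
        raise ValueError("peak outside searchable region")
    if peak_index - segment_start < 3 or segment_end - peak_index < 3:
        raise ValueError("segment shorter than 3 samples")
    if not (0 < section_fraction <= 1):
        raise ValueError("section_fraction must be in (0, 1]")

    pre = np.diff(x[segment_start : peak_index + 1])
    n_sec = max(1, int(round(section_fraction * pre.size)))
    sec = pre[pre.size - n_sec :]
    onset = segment_start + (pre.size - n_sec) + int(np.argmax(sec))

    post = np.diff(x[peak_index : segment_end + 1])
    n_sec = max(1, int(round(section_fraction * post.size)))
    sec = post[:n_sec]
    offset = peak_index + int(np.argmin(sec)) + 1
    return onset, offset


def st_angle(delta_y: float, convention: str = "magnitude") -> float:
    """ST angle in degrees from the amplitude step one sample after S.

    With the origin at S, the step to S* one sample later defines vectors
    a = (1, dy) and b = (0, dy); theta = arccos(a.b / |a||b|).  A unit
    rise (dy = 1) gives 45 degrees and a flat step the limiting 90
    degrees.  The default "magnitude" convention folds negative slopes
    into [0, 90]; "signed" maps dy = -1 to 135 degrees.
    """
    if convention not in ("magnitude", "signed"):
        raise ValueError(f"unknown convention {convention!r}")
    if delta_y == 0:
        return 90.0
    c = delta_y / math.hypot(1.0, delta_y)
    if convention == "magnitude":
        c = abs(c)
    return math.degrees(math.acos(c))


def extract_features(
    beat,
    interval: int,
    fs: float | None = None,
    section_fraction: float = 0.5,
    angle_convention: str = "magnitude",
) -> BeatFeatures:
    """Full feature extraction from a denoised beat.

    Parameters
    ----------
    beat : DenoisedBeat, ECGSignal or ndarray
        Denoised heartbeat samples.
    interval : int
        QRS window width in samples used for Q/S localisation.
    fs : float, optional
        Sampling frequency; taken from the beat when available.

    Raises
    ------
    ValueError
        Any stage failure propagates with the stage name prepended.
    """
    if isinstance(beat, DenoisedBeat):
        x = beat.samples
        fs = fs or beat.estimates.fs
    elif isinstance(beat, ECGSignal):
        x = beat.samples
        fs = fs or beat.fs
    else:
        x = np.asarray(beat, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from exc

    fid = stage("locate_r_q_s", locate_r_q_s, x, interval)
    z = stage("suppress_qrs", suppress_qrs, x, fid.q_index, fid.s_index)

    if fid.q_index < 1:
        raise ValueError("locate_p: no samples before Q")
    fid.p_index = int(np.argmax(z[: fid.q_index]))
    fid.p_value = float(z[fid.p_index])
    if fid.s_index + 1 >= x.size:
        raise ValueError("locate_t: no samples after S")
    fid.t_index = fid.s_index + 1 + int(np.argmax(z[fid.s_index + 1 :]))
    fid.t_value = float(z[fid.t_index])

    fid.p_onset_index, fid.p_offset_index = stage(
        "p_bounds", locate_wave_bounds, z, fid.p_index, 0, fid.q_index, section_fraction
    )
    fid.t_onset_index, fid.t_offset_index = stage(
        "t_bounds",
        locate_wave_bounds,
        z,
        fid.t_index,
        fid.s_index + 1,
        x.size - 1,
        section_fraction,
    )
    fid.p_onset_value = float(z[fid.p_onset_index])
    fid.p_offset_value = float(z[fid.p_offset_index])
    fid.t_onset_value = float(z[fid.t_onset_index])
    fid.t_offset_value = float(z[fid.t_offset_index])

    if fid.s_index + 1 >= x.size:
        raise ValueError("st_angle: S at the last sample")
    fid.s_star_index = fid.s_index + 1
    fid.s_star_value = float(x[fid.s_star_index])
    dy = fid.s_star_value - fid.s_value
    theta = st_angle(dy, convention=angle_convention)

    fid.baseline = fid.p_offset_value
    return BeatFeatures(
        p_amp=fid.p_value - fid.baseline,
        qrs_amp=fid.r_value - fid.baseline,
        t_amp=fid.t_value - fid.baseline,
        p_dur=(fid.p_offset_index - fid.p_onset_index) / fs,
        qrs_dur=(fid.s_index - fid.q_index) / fs,
        t_dur=(fid.t_offset_index - fid.t_onset_index) / fs,
        st_angle_deg=theta,
        fiducials=fid,
    )


def features_frame(features: list[BeatFeatures]):
    """One row per beat with all feature fields and fiducial indices."""
    import pandas as pd

    rows = []
    for bf in features:
        f = bf.fiducials
        rows.append(
            {
                "P_amp": bf.p_amp,
                "QRS_e": bf.qrs_amp,
                "T_amp": bf.t_amp,
                "P_dur": bf.p_dur,
                "QRS_dur": bf.qrs_dur,
                "T_dur": bf.t_dur,
                "ST_angle_deg": bf.st_angle_deg,
                "R_index": f.r_index,
                "Q_index": f.q_index,
                "S_index": f.s_index,
                "P_index": f.p_index,
                "T_index": f.t_index,
                "P_onset": f.p_onset_index,
                "P_offset": f.p_offset_index,
                "T_onset": f.t_onset_index,
                "T_offset": f.t_offset_index,
                "baseline": f.baseline,
            }
        )
    return pd.DataFrame(rows)
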