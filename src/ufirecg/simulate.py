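"""Fourier-series synthetic ECG generator with ground truth.

Each wave of the normal heartbeat is rendered as a pulse on the beat
period — a cosine lobe for the slow P and T waves (steepest slope exactly
at the wave boundaries, so onset/offset detection has a well-defined
ground truth) and a triangular pulse for the fast Q, R and S deflections —
then the beat is synthesised as a truncated Fourier series of the periodic
pulse train, mimicking the classic MATLAB Fourier-series ECG simulator.
Beats are exact periodic copies, so every fiducial index is known; zero
mean white Gaussian noise is added to meet a requested SNR, defined
against the mean-removed clean signal power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import BeatFeatures, FiducialSet, st_angle
from .signal import ECGSignal


@dataclass(frozen=True)
class WaveParams:
    """One wave of the heartbeat: amplitude (mV), duration (s), centre offset
    from the R peak (s), and pulse shape ("cosine" lobe or "triangle")."""

    amplitude: float
    duration: float
    offset: float
    shape: str


#: Normal-morphology defaults (amplitudes in mV, durations in seconds).
DEFAULT_WAVES: dict[str, WaveParams] = {
    "P": WaveParams(0.25, 0.09, -0.22, "cosine"),
    "Q": WaveParams(-0.025, 0.066, -0.088, "triangle"),
    "R": WaveParams(1.6, 0.11, 0.0, "triangle"),
    "S": WaveParams(-0.25, 0.066, 0.088, "triangle"),
    "T": WaveParams(0.35, 0.142, 0.30, "cosine"),
}


@dataclass
class SyntheticParams:
    """Study conditions for the synthetic generator."""

    heart_rate: float = 72.0
    fs: float = 360.0
    n_beats: int = 1
    snr_db: float | None = None
    seed: int = 0
    waves: dict[str, WaveParams] = field(default_factory=lambda: dict(DEFAULT_WAVES))
    #: harmonics kept in the Fourier synthesis; None keeps the full band up
    #: to Nyquist so rendered pulses (and hence fiducial truth) are exact
    n_harmonics: int | None = None

    @property
    def beat_samples(self) -> int:
        return int(round(self.fs * 60.0 / self.heart_rate))


@dataclass
class BeatTruth:
    """Ground-truth fiducials and features of one synthetic beat (beat-relative indices)."""

    fiducials: FiducialSet
    features: BeatFeatures


@dataclass
class SyntheticRecord:
    """Clean/noisy pair with per-beat ground truth."""

    clean: ECGSignal
    noisy: ECGSignal
    beat_bounds: list[tuple[int, int]]
    truth: list[BeatTruth]
    noise_variance: float
    params: SyntheticParams


def _pulse(t: np.ndarray, wave: WaveParams, center: float) -> np.ndarray:
    half = wave.duration / 2.0
    u = t - center
    mask = np.abs(u) <= half
    out = np.zeros_like(t)
    if wave.shape == "cosine":
        out[mask] = wave.amplitude * np.cos(np.pi * u[mask] / wave.duration)
    elif wave.shape == "triangle":
        out[mask] = wave.amplitude * (1.0 - np.abs(u[mask]) / half)
    else:
        raise ValueError(f"unknown wave shape {wave.shape!r}")
    return out


def _validate_layout(params: SyntheticParams, period: float) -> None:
    order = sorted(params.waves.items(), key=lambda kv: kv[1].offset)
    spans = []
    for name, w in order:
        if w.duration <= 0 or w.duration >= period:
            raise ValueError(f"wave {name}: duration {w.duration} infeasible for period {period}")
        lo = w.offset - w.duration / 2.0
        hi = w.offset + w.duration / 2.0
        spans.append((name, lo, hi))
    for (n1, _, hi1), (n2, lo2, _) in zip(spans, spans[1:]):
        if lo2 < hi1 - 1e-12:
            raise ValueError(f"waves {n1} and {n2} overlap")
    lo_all = spans[0][1] + period / 2.0
    hi_all = spans[-1][2] + period / 2.0
    if lo_all < 0 or hi_all > period:
        raise ValueError("wave layout extends outside the beat period")


def _render_beat(params: SyntheticParams) -> np.ndarray:
    L = params.beat_samples
    period = L / params.fs
    _validate_layout(params, period)
    t = np.arange(L) / params.fs
    r_time = (L // 2) / params.fs
    beat = np.zeros(L)
    for w in params.waves.values():
        beat += _pulse(t, w, r_time + w.offset)
    # Fourier synthesis of the periodic pulse train, optionally bandlimited
    if params.n_harmonics is not None and params.n_harmonics < L // 2:
        spec = np.fft.rfft(beat)
        spec[params.n_harmonics + 1 :] = 0.0
        beat = np.fft.irfft(spec, L)
    return beat


def _beat_truth(beat: np.ndarray, params: SyntheticParams) -> BeatTruth:
    L = params.beat_samples
    fs = params.fs
    r_time = (L // 2) / fs

    def span(name: str) -> tuple[int, int]:
        w = params.waves[name]
        lo = int(round((r_time + w.offset - w.duration / 2) * fs))
        hi = int(round((r_time + w.offset + w.duration / 2) * fs))
        return max(0, lo), min(L - 1, hi)

    def peak(name: str) -> int:
        lo, hi = span(name)
        seg = beat[lo : hi + 1]
        w = params.waves[name]
        k = int(np.argmax(seg)) if w.amplitude >= 0 else int(np.argmin(seg))
        return lo + k

    r = peak("R")
    q = peak("Q")
    s = peak("S")
    p = peak("P")
    tt = peak("T")
    p_on, p_off = span("P")
    t_on, t_off = span("T")
    dy = float(beat[s + 1] - beat[s])
    fid = FiducialSet(
        r_index=r, r_value=float(beat[r]),
        q_index=q, q_value=float(beat[q]),
        s_index=s, s_value=float(beat[s]),
        p_index=p, p_value=float(beat[p]),
        t_index=tt, t_value=float(beat[tt]),
        p_onset_index=p_on, p_offset_index=p_off,
        t_onset_index=t_on, t_offset_index=t_off,
        p_onset_value=float(beat[p_on]), p_offset_value=float(beat[p_off]),
        t_onset_value=float(beat[t_on]), t_offset_value=float(beat[t_off]),
        s_star_index=s + 1, s_star_value=float(beat[s + 1]),
        baseline=0.0,
    )
    feats = BeatFeatures(
        p_amp=float(beat[p]),
        qrs_amp=float(beat[r]),
        t_amp=float(beat[tt]),
        p_dur=params.waves["P"].duration,
        qrs_dur=(s - q) / fs,
        t_dur=params.waves["T"].duration,
        st_angle_deg=st_angle(dy),
        fiducials=fid,
    )
    return BeatTruth(fiducials=fid, features=feats)


def generate(params: SyntheticParams) -> SyntheticRecord:
    """Generate a synthetic record of ``params.n_beats`` identical clean beats
    plus seeded AWGN meeting ``params.snr_db`` (noiseless when None)."""
    if params.n_beats < 1:
        raise ValueError("need at least one beat")
    beat = _render_beat(params)
    L = params.beat_samples
    clean = np.tile(beat, params.n_beats)
    truth0 = _beat_truth(beat, params)
    truth = [truth0] * params.n_beats
    bounds = [(k * L, (k + 1) * L) for k in range(params.n_beats)]

    if params.snr_db is None:
        noisy = clean.copy()
        sigma2 = 0.0
    else:
        power = float(np.var(clean))  # mean-removed clean power
        sigma2 = power / 10.0 ** (params.snr_db / 10.0)
        rng = np.random.default_rng(params.seed)
        noisy = clean + rng.normal(0.0, np.sqrt(sigma2), clean.size)

    label = f"synthetic hr={params.heart_rate} snr={params.snr_db} seed={params.seed}"
    return SyntheticRecord(
        clean=ECGSignal(clean, params.fs, label + " (clean)"),
        noisy=ECGSignal(noisy, params.fs, label),
        beat_bounds=bounds,
        truth=truth,
        noise_variance=sigma2,
        params=params,
    )


def snr_sweep(
    params: SyntheticParams,
    snr_list: list[float] | None = None,
    seeds: list[int] = (0,),
) -> dict[tuple[float, int], SyntheticRecord]:
    """One record per (SNR, seed); default grid 0..85 dB in 5 dB steps (18 points)."""
    if snr_list is None:
        snr_list = list(np.arange(0.0, 86.0, 5.0))
    if not snr_list or not seeds:
        raise ValueError("snr_list and seeds must be nonempty")
    out = {}
    for seed in seeds:
        for snr in snr_list:
            # fold the SNR point into the stream so records are independent
            p = replace(params, snr_db=float(snr), seed=_mix_seed(seed, snr))
            out[(float(snr), int(seed))] = generate(p)
    return out


def _mix_seed(seed: int, snr_db: float) -> int:
    return (int(seed) * 1_000_003 + int(round(snr_db * 100))) % (2**31 - 1)
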