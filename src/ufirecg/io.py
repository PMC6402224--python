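"""Signal file I/O: plain CSV and WFDB format-212 records.

The WFDB reader handles the header (.hea) and packed 12-bit format-212
signal (.dat) layout used by the MIT-BIH Arrhythmia Database (360 Hz,
11-bit over 10 mV), applying per-channel gain and baseline to return
millivolts.  A matching writer exists so codec round-trips can be
exercised without any database download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import ECGSignal


def read_csv_signal(path, fs: float | None = None, column: str | None = None) -> ECGSignal:
    """Read one sample per row; header optional; fs from argument or 'fs' column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    # a headerless single column of numbers parses with the first value as header
    if df.columns.size == 1 and df.columns[0].replace(".", "", 1).replace("-", "", 1).isdigit():
        df = pd.read_csv(path, header=None, names=["sample"], float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: header-only file contains no samples")
    col = column or ("sample" if "sample" in df.columns else df.columns[0])
    raw = pd.to_numeric(df[col], errors="coerce")
    if raw.isna().any():
        line = int(raw.index[raw.isna()][0]) + 2  # 1-based + header line
        raise ValueError(f"{path}: non-numeric sample at line {line}")
    if fs is None:
        if "fs" in df.columns:
            fs = float(df["fs"].iloc[0])
        else:
            raise ValueError("sampling frequency not given and no 'fs' column present")
    return ECGSignal(raw.to_numpy(dtype=float), fs=fs, label=path.stem)


def write_csv_signal(signal: ECGSignal, path) -> None:
    """Lossless (full double precision) one-sample-per-row CSV."""
    df = pd.DataFrame({"sample": signal.samples})
    df["fs"] = signal.fs
    df.to_csv(path, index=False, float_format="%.17g")


@dataclass
class _SignalSpec:
    filename: str
    fmt: int
    gain: float
    baseline: int
    adc_res: int
    adc_zero: int
    description: str


def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_name, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    specs = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        filename, fmt = tok[0], tok[1]
        if "x" in fmt or ":" in fmt or "+" in fmt:
            raise ValueError(f"unsupported format modifier in {fmt!r}")
        fmt = int(fmt)
        gain_tok = tok[2] if len(tok) > 2 else "200"
        units = "mV"
        if "/" in gain_tok:
            gain_tok, units = gain_tok.split("/", 1)
        baseline = None
        if "(" in gain_tok:
            gain_tok, rest = gain_tok.split("(", 1)
            baseline = int(rest.rstrip(")"))
        gain = float(gain_tok) or 200.0
        adc_res = int(tok[3]) if len(tok) > 3 else 12
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        description = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(specs)}"
        specs.append(
            _SignalSpec(filename, fmt, gain, baseline, adc_res, adc_zero, description)
        )
    return record_name, n_sig, fs, n_samples, specs


def _decode_212(raw: np.ndarray, n_values: int) -> np.ndarray:
    if raw.size % 3:
        raw = raw[: raw.size - raw.size % 3]
    b0 = raw[0::3].astype(np.int32)
    b1 = raw[1::3].astype(np.int32)
    b2 = raw[2::3].astype(np.int32)
    s0 = ((b1 & 0x0F) << 8) | b0
    s1 = ((b1 & 0xF0) << 4) | b2
    out = np.empty(2 * b0.size, dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    out[out > 2047] -= 4096  # two's-complement 12-bit
    if out.size < n_values:
        raise ValueError(
            f"truncated format-212 file: {out.size} values present, {n_values} expected"
        )
    return out[:n_values]


def read_wfdb(record_path, channel: str = "MLII") -> ECGSignal:
    """Read one lead of a WFDB format-212 record, in millivolts.

    ``record_path`` is the path without extension (header at .hea, signal
    at the filename the header names).  Raises with the available leads
    listed when ``channel`` is not present.
    """
    record_path = Path(record_path)
    hea = record_path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    record_name, n_sig, fs, n_samples, specs = _parse_header(hea)
    names = [sp.description for sp in specs]
    if channel not in names:
        raise ValueError(f"lead {channel!r} not in record; available leads: {names}")
    ch = names.index(channel)
    fmts = {sp.fmt for sp in specs}
    if fmts != {212}:
        raise ValueError(f"unsupported WFDB format code(s) {sorted(fmts)}; only 212 is handled")
    dat = record_path.parent / specs[ch].filename
    raw = np.fromfile(dat, dtype=np.uint8)
    if n_samples == 0:
        n_samples = (raw.size // 3) * 2 // n_sig
    values = _decode_212(raw, n_samples * n_sig).reshape(n_samples, n_sig)
    sp = specs[ch]
    mv = (values[:, ch] - sp.baseline) / sp.gain
    return ECGSignal(mv.astype(float), fs=fs, label=f"{record_name}/{channel}")


def write_wfdb(
    record_path,
    signals: np.ndarray,
    fs: float,
    gains=(200.0,),
    baselines=(1024,),
    channel_names=("MLII",),
    adc_res: int = 11,
) -> None:
    """Write a format-212 record (header + packed .dat) from mV signals."""
    record_path = Path(record_path)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] > signals.shape[1]:
        signals = signals.T
    n_sig, n_samples = signals.shape
    adc = np.empty((n_samples, n_sig), dtype=np.int32)
    for ch in range(n_sig):
        adc[:, ch] = np.round(signals[ch] * gains[ch] + baselines[ch]).astype(np.int32)
    if adc.min() < -2048 or adc.max() > 2047:
        raise ValueError("samples exceed the 12-bit range of format 212")
    flat = adc.reshape(-1)
    if flat.size % 2:
        flat = np.concatenate([flat, [0]])
    u = np.where(flat < 0, flat + 4096, flat).astype(np.uint32)
    s0, s1 = u[0::2], u[1::2]
    raw = np.empty(3 * s0.size, dtype=np.uint8)
    raw[0::3] = s0 & 0xFF
    raw[1::3] = ((s1 >> 8) << 4) | (s0 >> 8)
    raw[2::3] = s1 & 0xFF
    dat_name = record_path.name + ".dat"
    (record_path.parent / dat_name).write_bytes(raw.tobytes())
    lines = [f"{record_path.name} {n_sig} {fs:g} {n_samples}"]
    for ch in range(n_sig):
        lines.append(
            f"{dat_name} 212 {gains[ch]:g}({baselines[ch]})/mV {adc_res} "
            f"{baselines[ch]} {adc[0, ch]} 0 0 {channel_names[ch]}"
        )
    record_path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
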