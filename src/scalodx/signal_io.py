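"""Reading, segmenting and conditioning single-channel ECG signals.

Supports WFDB records (header + signal file, formats 212 and 16) and plain
CSV signals.  Records are cut into fixed-duration windows, linearly
detrended, and optionally resampled to a common rate so that wavelet scales
carry the same meaning across source databases.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import resample_poly
from fractions import Fraction

__all__ = [
    "EcgRecord",
    "Segment",
    "read_wfdb",
    "read_csv_signal",
    "write_csv_signal",
    "segment_record",
    "detrend",
    "resample",
]


@dataclass(frozen=True)
class EcgRecord:
    """A raw single-channel ECG trace in physical units (mV)."""

    samples: np.ndarray
    fs: float
    record_id: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class Segment:
    """One fixed-duration ECG window — the unit of analysis.

    ``label`` is one of {"SR", "PEA", "VF", "VT"} when known.
    ``start_index`` is the 0-based sample offset in the source record.
    """

    samples: np.ndarray
    fs: float
    label: Optional[str] = None
    record_id: str = ""
    start_index: int = 0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("segment samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("segment samples must be finite")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs


# ---------------------------------------------------------------------------
# WFDB reading (formats 212 and 16)
# ---------------------------------------------------------------------------

def _parse_gain(tok: str) -> tuple[float, Optional[int]]:
    """Parse a WFDB gain token ``gain(baseline)/units``."""
    tok = tok.split("/")[0]
    m = re.match(r"^(-?[\d.]+)(?:\((-?\d+)\))?$", tok)
    if m is None:
        raise ValueError(f"cannot parse WFDB gain specification {tok!r}")
    gain = float(m.group(1))
    baseline = int(m.group(2)) if m.group(2) is not None else None
    return gain, baseline


def read_wfdb(path: str, channel_index: int = 0) -> EcgRecord:
    """Read one channel of a WFDB record into physical units (mV).

    ``path`` is the record path without extension (or the ``.hea`` file).
    Handles signal formats 212 (packed 12-bit pairs) and 16 (little-endian
    int16), with all channels multiplexed into a single signal file.
    """
    if path.endswith(".hea"):
        path = path[:-4]
    hea = path + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"WFDB header not found: {hea}")

    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    rec_tokens = lines[0].split()
    record_name = rec_tokens[0].split("/")[0]
    n_sig = int(rec_tokens[1])
    fs = float(rec_tokens[2]) if len(rec_tokens) > 2 else 250.0
    n_samples = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0

    if not 0 <= channel_index < n_sig:
        raise IndexError(
            f"channel_index {channel_index} out of range for {n_sig} signal(s)"
        )
    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) < n_sig:
        raise ValueError(f"corrupt WFDB header {hea}: missing signal lines")

    fnames, fmts, gains, baselines, zeros, descs = [], [], [], [], [], []
    for ln in sig_lines:
        toks = ln.split()
        if len(toks) < 2:
            raise ValueError(f"corrupt WFDB signal line: {ln!r}")
        fnames.append(toks[0])
        fmts.append(toks[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = _parse_gain(toks[2]) if len(toks) > 2 else (200.0, None)
        if gain == 0:
            gain = 200.0  # WFDB convention: 0 means default
        gains.append(gain)
        adc_zero = int(toks[4]) if len(toks) > 4 else 0
        zeros.append(adc_zero)
        baselines.append(baseline if baseline is not None else adc_zero)
        descs.append(" ".join(toks[8:]) if len(toks) > 8 else f"ch{len(descs)}")

    if len(set(fnames)) != 1:
        raise ValueError("multi-file WFDB records are not supported")
    dat = os.path.join(os.path.dirname(hea), fnames[0])
    if not os.path.exists(dat):
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    fmt = fmts[channel_index]
    if any(f != fmt for f in fmts):
        raise ValueError("mixed signal formats in one file are not supported")

    raw = np.fromfile(dat, dtype=np.uint8)
    if fmt == "16":
        digital = raw.view("<i2").astype(np.int64)
        digital = digital[: (digital.size // n_sig) * n_sig].reshape(-1, n_sig)
    elif fmt == "212":
        # three bytes encode two 12-bit two's-complement samples
        usable = (raw.size // 3) * 3
        b = raw[:usable].reshape(-1, 3).astype(np.int64)
        first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        digital = np.empty(2 * b.shape[0], dtype=np.int64)
        digital[0::2] = first
        digital[1::2] = second
        digital = digital[: (digital.size // n_sig) * n_sig].reshape(-1, n_sig)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt!r}")

    if n_samples:
        digital = digital[:n_samples]
    col = digital[:, channel_index]
    physical = (col - baselines[channel_index]) / gains[channel_index]
    return EcgRecord(
        samples=physical,
        fs=fs,
        record_id=record_name,
        channel=descs[channel_index],
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_csv_signal(path: str, fs: Optional[float] = None) -> EcgRecord:
    """Read a one- or two-column numeric CSV as an ECG record.

    Two columns are interpreted as (time s, amplitude mV) and the rate is
    inferred from the median sample spacing; spacing must be uniform to
    within 1% unless ``fs`` is given explicitly.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"CSV signal file not found: {path}")
    try:
        data = np.genfromtxt(path, delimiter=",", comments="#")
    except ValueError as exc:
        raise ValueError(f"non-numeric data in {path}: {exc}") from exc
    data = np.atleast_2d(data)
    if data.shape[0] == 1 and data.shape[1] > 2:
        data = data.T
    # a header row parses to NaN; drop leading all-NaN rows
    while data.shape[0] and np.all(np.isnan(data[0])):
        data = data[1:]
    if data.size == 0:
        raise ValueError(f"no numeric rows in {path}")
    if np.any(np.isnan(data)):
        raise ValueError(f"non-numeric rows in {path}")

    rid = os.path.splitext(os.path.basename(path))[0]
    if data.shape[1] == 1:
        if fs is None:
            raise ValueError("fs is required for a single-column CSV")
        return EcgRecord(samples=data[:, 0], fs=fs, record_id=rid)
    if data.shape[1] != 2:
        raise ValueError(f"expected 1 or 2 columns, got {data.shape[1]}")

    t, x = data[:, 0], data[:, 1]
    if fs is None:
        dt = np.diff(t)
        med = np.median(dt)
        if med <= 0:
            raise ValueError("time column must be strictly increasing")
        if np.any(np.abs(dt - med) > 0.01 * med):
            raise ValueError(
                "non-uniform time spacing (>1% deviation); pass fs explicitly"
            )
        fs = 1.0 / med
    return EcgRecord(samples=x, fs=fs, record_id=rid)


def write_csv_signal(rec: EcgRecord | Segment, path: str) -> None:
    """Write a record or segment as a two-column (time, amplitude) CSV."""
    t = np.arange(rec.samples.size) / rec.fs
    np.savetxt(
        path,
        np.column_stack([t, rec.samples]),
        delimiter=",",
        header="time_s,amplitude_mv",
        comments="",
        fmt="%.9g",
    )


# ---------------------------------------------------------------------------
# Segmentation and conditioning
# ---------------------------------------------------------------------------

def segment_record(
    rec: EcgRecord,
    duration: float = 5.0,
    overlap: float = 0.0,
    label: Optional[str] = None,
) -> list[Segment]:
    """Tile a record into ``duration``-second windows.

    Windows are half-open ``[start, start + n)`` in samples; a trailing
    remainder shorter than one window is dropped.  ``overlap`` (seconds)
    produces sliding windows; the default 0 tiles the record.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0 <= overlap < duration:
        raise ValueError("overlap must satisfy 0 <= overlap < duration")
    n = int(round(rec.fs * duration))
    step = n - int(round(rec.fs * overlap))
    out: list[Segment] = []
    for start in range(0, rec.samples.size - n + 1, step):
        out.append(
            Segment(
                samples=rec.samples[start : start + n].copy(),
                fs=rec.fs,
                label=label,
                record_id=rec.record_id,
                start_index=start,
            )
        )
    return out


def detrend(seg: Segment) -> Segment:
    """Subtract the least-squares straight line (intercept + slope vs time).

    Idempotent and linear; the output has mean ~0.
    """
    x = seg.samples
    t = seg.times
    # orthogonal projection onto {1, t}
    tc = t - t.mean()
    denom = float(tc @ tc)
    slope = float(tc @ x) / denom if denom > 0 else 0.0
    fitted = x.mean() + slope * tc
    return replace(seg, samples=x - fitted)


def resample(seg: Segment, target_fs: float) -> Segment:
    """Band-limited resampling to ``target_fs`` (no-op if rates match)."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == seg.fs:
        return seg
    frac = Fraction(target_fs / seg.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    y = resample_poly(seg.samples, up, down)
    n_target = int(round(seg.samples.size * target_fs / seg.fs))
    if y.size > n_target:
        y = y[:n_target]
    elif y.size < n_target:
        y = np.pad(y, (0, n_target - y.size))
    return replace(
        seg,
        samples=y,
        fs=target_fs,
        start_index=int(round(seg.start_index * target_fs / seg.fs)),
    )
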