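"""Seeded synthetic generator of labeled 5-s ECG segments, four rhythms.

The generator emulates the gross morphology and spectral content of the
four rhythm classes the discrimination problem concerns, not their clinical
physiology:

  SR   Gaussian-pulse QRS train at ~1.2 Hz with small T-wave bumps (~1 mV)
  PEA  low-amplitude (~0.15 mV) broad slow complexes at ~0.8 Hz, jittered
  VT   high-amplitude (~1.5 mV) regular quasi-sinusoid at ~3.3 Hz
  VF   disorganized oscillation whose instantaneous frequency wanders
       uniformly in 4-7 Hz (random-walk phase modulation) with amplitude
       modulation (~1 mV)

White Gaussian noise (sd 0.05 mV) is added and each segment is linearly
detrended.  Per-segment seeds are derived deterministically from the
dataset seed via CRC-32 of "seed:label:index", so datasets are fully
reproducible and individual segments re-generable in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .signal_io import Segment, detrend

__all__ = [
    "RhythmSpec",
    "GeneratorConfig",
    "DEFAULT_RHYTHMS",
    "gen_segment",
    "gen_dataset",
    "derive_seed",
]

CLASSES: tuple[str, ...] = ("SR", "PEA", "VF", "VT")


@dataclass(frozen=True)
class RhythmSpec:
    """Waveform recipe for one rhythm class."""

    label: str
    rate_hz: float
    rate_jitter: float  # fractional sd of beat-to-beat timing
    kind: str  # pulse_train | quasi_sinusoid | phase_modulated
    amplitude_mv: float
    amplitude_jitter: float  # fractional sd per event/cycle
    noise_sd_mv: float = 0.05
    pulse_width_s: float = 0.03  # Gaussian sd of a pulse (pulse_train only)
    freq_band_hz: tuple[float, float] = (4.0, 7.0)  # phase_modulated only

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.amplitude_mv <= 0 or self.noise_sd_mv < 0:
            raise ValueError("rate and amplitude must be positive, noise sd >= 0")


DEFAULT_RHYTHMS: dict[str, RhythmSpec] = {
    "SR": RhythmSpec(
        label="SR", rate_hz=1.2, rate_jitter=0.04, kind="pulse_train",
        amplitude_mv=1.0, amplitude_jitter=0.08, pulse_width_s=0.025,
    ),
    "PEA": RhythmSpec(
        label="PEA", rate_hz=0.8, rate_jitter=0.12, kind="pulse_train",
        amplitude_mv=0.15, amplitude_jitter=0.15, pulse_width_s=0.12,
    ),
    "VT": RhythmSpec(
        label="VT", rate_hz=3.3, rate_jitter=0.03, kind="quasi_sinusoid",
        amplitude_mv=1.5, amplitude_jitter=0.05,
    ),
    "VF": RhythmSpec(
        label="VF", rate_hz=5.5, rate_jitter=0.0, kind="phase_modulated",
        amplitude_mv=1.0, amplitude_jitter=0.0, freq_band_hz=(4.0, 7.0),
    ),
}


@dataclass(frozen=True)
class GeneratorConfig:
    fs: float = 250.0
    duration: float = 5.0
    seed: int = 0
    n_per_class: int = 40

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")


def derive_seed(dataset_seed: int, label: str, index: int) -> int:
    """Stable per-segment seed: CRC-32 of "seed:label:index", < 2^31."""
    return zlib.crc32(f"{dataset_seed}:{label}:{index}".encode()) & 0x7FFFFFFF


def _pulse_train(rng, spec: RhythmSpec, t: np.ndarray, fs: float) -> np.ndarray:
    """Gaussian-pulse events at the base rate with timing/amplitude jitter.

    SR additionally gets a small broad T-wave bump after each QRS pulse.
    """
    period = 1.0 / spec.rate_hz
    x = np.zeros_like(t)
    centers = []
    c = rng.uniform(0, period)
    while c < t[-1] + period:
        centers.append(c)
        c += period * (1.0 + spec.rate_jitter * rng.standard_normal())
    for c in centers:
        amp = spec.amplitude_mv * (1.0 + spec.amplitude_jitter * rng.standard_normal())
        x += amp * np.exp(-((t - c) ** 2) / (2.0 * spec.pulse_width_s**2))
        if spec.label == "SR":
            # low, broad repolarization bump trailing the QRS
            x += 0.15 * amp * np.exp(-((t - c - 0.25) ** 2) / (2.0 * 0.08**2))
    return x


def _quasi_sinusoid(rng, spec: RhythmSpec, t: np.ndarray) -> np.ndarray:
    """Regular monomorphic oscillation with a small second harmonic."""
    f = spec.rate_hz * (1.0 + spec.rate_jitter * rng.standard_normal())
    phase = 2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
    amp = spec.amplitude_mv * (1.0 + spec.amplitude_jitter * rng.standard_normal())
    return amp * (np.sin(phase) + 0.15 * np.sin(2 * phase + rng.uniform(0, 2 * np.pi)))


def _phase_modulated(rng, spec: RhythmSpec, t: np.ndarray, fs: float) -> np.ndarray:
    """Oscillation whose instantaneous frequency random-walks in the band."""
    lo, hi = spec.freq_band_hz
    n = t.size
    # reflected random walk for the instantaneous frequency
    steps = rng.standard_normal(n) * (0.8 / np.sqrt(fs))
    f_inst = np.empty(n)
    f = rng.uniform(lo + 0.5, hi - 0.5)
    for i in range(n):
        f += steps[i]
        if f < lo:
            f = 2 * lo - f
        elif f > hi:
            f = 2 * hi - f
        f_inst[i] = f
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
    am = 1.0 - 0.35 * np.sin(
        2.0 * np.pi * rng.uniform(0.4, 0.9) * t + rng.uniform(0, 2 * np.pi)
    ) ** 2
    return spec.amplitude_mv * am * np.sin(phase)


def gen_segment(
    spec: RhythmSpec,
    cfg: GeneratorConfig = GeneratorConfig(),
    seed: Optional[int] = None,
) -> Segment:
    """Generate one detrended labeled segment; same seed, same samples."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = int(round(cfg.fs * cfg.duration))
    t = np.arange(n) / cfg.fs
    if spec.kind == "pulse_train":
        x = _pulse_train(rng, spec, t, cfg.fs)
    elif spec.kind == "quasi_sinusoid":
        x = _quasi_sinusoid(rng, spec, t)
    elif spec.kind == "phase_modulated":
        x = _phase_modulated(rng, spec, t, cfg.fs)
    else:
        raise ValueError(f"unknown waveform kind {spec.kind!r}")
    x = x + spec.noise_sd_mv * rng.standard_normal(n)
    seg = Segment(
        samples=x,
        fs=cfg.fs,
        label=spec.label,
        record_id=f"synthetic-{spec.label}",
        start_index=0,
    )
    return detrend(seg)


def gen_dataset(
    cfg: GeneratorConfig = GeneratorConfig(),
    rhythms: Optional[dict[str, RhythmSpec]] = None,
) -> list[Segment]:
    """n_per_class segments per rhythm, deterministically seeded, shuffled."""
    if cfg.n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rhythms = rhythms or DEFAULT_RHYTHMS
    segments: list[Segment] = []
    for label in CLASSES:
        if label not in rhythms:
            continue
        for i in range(cfg.n_per_class):
            seg = gen_segment(rhythms[label], cfg, derive_seed(cfg.seed, label, i))
            segments.append(replace(seg, record_id=f"synthetic-{label}-{i:03d}"))
    order = np.random.default_rng(cfg.seed).permutation(len(segments))
    return [segments[i] for i in order]
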