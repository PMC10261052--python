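"""Gabor wavelet scalograms modulated by pseudo-differential-like operators.

The transform of a detrended segment f is

    Wf(a, b) = (1/sqrt(a)) * integral f(t) * conj(psi((t - b)/a)) dt

with the Gabor mother wavelet

    psi(t) = (2*pi*sigma^2)^(-1/2) * exp(-t^2 / (2 sigma^2)) * exp(i w0 t).

A scale-dependent multiplier L(a) (acting like a Fourier multiplier — e.g.
L(a) = 1/a approximates a fractional derivative) and an elementwise
nonlinearity H(y) = |y|^q then give the scalogram

    E(a, b) = H( L(a) * Wf(a, b) ).

With w0 = 2 the mother-wavelet centre frequency is w0/(2 pi a) = 1/(pi a),
so the scale axis converts to Hz by F(a) = 1/(pi a).  The default operating
point L(a) = 1/a with q = 1/4 amplifies small-amplitude coefficients, which
is what separates the visually similar abnormal rhythms (PEA vs VF/VT);
L(a) = 1 with q = 2 is the conventional energy scalogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.signal import fftconvolve

from .signal_io import Segment

__all__ = [
    "GaborParams",
    "PseudoDiffSpec",
    "NonlinearSpec",
    "ScaleGrid",
    "Scalogram",
    "mother_wavelet",
    "gabor_cwt",
    "gabor_cwt_direct",
    "apply_pseudo_diff",
    "apply_nonlinear",
    "compute_scalogram",
    "default_scale_grid",
]

#: Hz-per-(1/a) conversion of the scale axis for the default w0 = 2.
FREQ_CONVENTION = 1.0 / np.pi


@dataclass(frozen=True)
class GaborParams:
    """Mother-wavelet parameters: Gaussian width sigma, modulation w0 (rad)."""

    sigma: float = 1.0
    omega0: float = 2.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


_PSEUDO_DIFF_FORMS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {
    "identity": lambda a, g: np.ones_like(a),
    "inverse": lambda a, g: 1.0 / a,
    "linear": lambda a, g: a,
    "inverse_squared": lambda a, g: 1.0 / a**2,
    "inverse_sqrt": lambda a, g: 1.0 / np.sqrt(a),
    "power": lambda a, g: a**g,
}


@dataclass(frozen=True)
class PseudoDiffSpec:
    """The scale multiplier L(a); ``form='power'`` uses exponent ``gamma``."""

    form: str = "inverse"
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in _PSEUDO_DIFF_FORMS:
            raise ValueError(
                f"unknown operator form {self.form!r}; "
                f"choose from {sorted(_PSEUDO_DIFF_FORMS)}"
            )

    def __call__(self, scales: np.ndarray) -> np.ndarray:
        scales = np.asarray(scales, dtype=float)
        if np.any(scales <= 0):
            raise ValueError("scales must be positive")
        return _PSEUDO_DIFF_FORMS[self.form](scales, self.gamma)


@dataclass(frozen=True)
class NonlinearSpec:
    """Elementwise nonlinearity H(y) = |y|^q applied after L(a)."""

    q: float = 0.25

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise ValueError("nonlinearity exponent q must be positive")

    def __call__(self, m: np.ndarray) -> np.ndarray:
        return np.abs(m) ** self.q


@dataclass(frozen=True)
class ScaleGrid:
    """Strictly increasing scales with their Hz and time axes."""

    scales: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if scales.size == 0:
            raise ValueError("scale grid is empty")
        if np.any(scales <= 0) or np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be positive and strictly increasing")
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "times", times)

    @property
    def freqs(self) -> np.ndarray:
        """F(a) = 1/(pi a) in Hz, strictly decreasing in a."""
        return FREQ_CONVENTION / self.scales

    @property
    def n_scales(self) -> int:
        return self.scales.size


def default_scale_grid(
    seg: Segment,
    fmin: float = 0.5,
    fmax: float = 32.0,
    n_scales: int = 64,
) -> ScaleGrid:
    """Log-spaced scales covering ``fmin``–``fmax`` Hz (PEA through VF)."""
    if not 0 < fmin < fmax:
        raise ValueError("need 0 < fmin < fmax")
    freqs = np.geomspace(fmax, fmin, n_scales)  # decreasing f -> increasing a
    scales = FREQ_CONVENTION / freqs
    return ScaleGrid(scales=scales, times=seg.times)


@dataclass(frozen=True)
class Scalogram:
    """E(a, b) = H(L(a) Wf(a, b)) on a scale grid; nonnegative by design."""

    E: np.ndarray
    grid: ScaleGrid
    params: GaborParams
    operator: PseudoDiffSpec
    nonlinearity: NonlinearSpec
    segment_ref: str = ""

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        if E.shape != (self.grid.n_scales, self.grid.times.size):
            raise ValueError(
                f"scalogram shape {E.shape} inconsistent with grid "
                f"({self.grid.n_scales}, {self.grid.times.size})"
            )
        if np.any(E < 0):
            raise ValueError("scalogram values must be nonnegative")
        object.__setattr__(self, "E", E)


def mother_wavelet(t, params: GaborParams = GaborParams()):
    """Evaluate the Gabor mother wavelet psi(t); accepts scalars or arrays."""
    t = np.asarray(t, dtype=float)
    s2 = params.sigma**2
    env = np.exp(-(t**2) / (2.0 * s2)) / np.sqrt(2.0 * np.pi * s2)
    return env * np.exp(1j * params.omega0 * t)


def gabor_cwt(
    seg: Segment,
    grid: ScaleGrid,
    params: GaborParams = GaborParams(),
    support_sigmas: float = 8.0,
) -> np.ndarray:
    """Gabor wavelet coefficients Wf(a, b) for every grid scale and sample.

    Implemented as FFT cross-correlation with the sampled conjugate wavelet,
    truncated at ``support_sigmas``*sigma*a (Gaussian tail ~1e-14 at the
    default 8), zero-padded at the boundaries, with dt = 1/fs as the Riemann
    weight.  Agrees with :func:`gabor_cwt_direct` to ~1e-12 relative error.
    """
    if seg.samples.size == 0:
        raise ValueError("cannot transform a zero-length segment")
    f = seg.samples
    dt = 1.0 / seg.fs
    n = f.size
    out = np.empty((grid.n_scales, n), dtype=complex)
    for k, a in enumerate(grid.scales):
        half = min(n, int(np.ceil(support_sigmas * params.sigma * a * seg.fs)))
        m = np.arange(-half, half + 1)
        kernel = np.conj(mother_wavelet(m * dt / a, params))
        # cross-correlation = convolution with the reversed kernel
        out[k] = fftconvolve(f, kernel[::-1], mode="same") * (dt / np.sqrt(a))
    return out


def gabor_cwt_direct(
    seg: Segment,
    grid: ScaleGrid,
    params: GaborParams = GaborParams(),
) -> np.ndarray:
    """Direct Riemann double-sum evaluation of Wf(a, b) — the slow oracle."""
    f = seg.samples
    t = seg.times
    dt = 1.0 / seg.fs
    out = np.empty((grid.n_scales, t.size), dtype=complex)
    for k, a in enumerate(grid.scales):
        # (t - b)/a for all pairs; columns indexed by b
        arg = (t[:, None] - t[None, :]) / a
        out[k] = (f @ np.conj(mother_wavelet(arg, params))) * (dt / np.sqrt(a))
    return out


def apply_pseudo_diff(
    Wf: np.ndarray, grid: ScaleGrid, operator: PseudoDiffSpec
) -> np.ndarray:
    """Multiply row k (scale a_k) by L(a_k)."""
    Wf = np.asarray(Wf)
    if Wf.shape[0] != grid.n_scales:
        raise ValueError("coefficient rows do not match the scale grid")
    return operator(grid.scales)[:, None] * Wf


def apply_nonlinear(M: np.ndarray, nonlinearity: NonlinearSpec) -> np.ndarray:
    """Elementwise H(y) = |y|^q."""
    return nonlinearity(np.asarray(M))


def compute_scalogram(
    seg: Segment,
    grid: Optional[ScaleGrid] = None,
    params: GaborParams = GaborParams(),
    operator: PseudoDiffSpec = PseudoDiffSpec(),
    nonlinearity: NonlinearSpec = NonlinearSpec(),
) -> Scalogram:
    """Full pipeline E(a, b) = H(L(a) Wf(a, b)) for one segment."""
    if grid is None:
        grid = default_scale_grid(seg)
    Wf = gabor_cwt(seg, grid, params)
    E = apply_nonlinear(apply_pseudo_diff(Wf, grid, operator), nonlinearity)
    ref = f"{seg.record_id}@{seg.start_index}" if seg.record_id else ""
    return Scalogram(
        E=E,
        grid=grid,
        params=params,
        operator=operator,
        nonlinearity=nonlinearity,
        segment_ref=ref,
    )
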