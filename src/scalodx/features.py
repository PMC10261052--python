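"""Scalogram characterization: NSI/NTI centroid series and the 16 statistics.

NSI(b) is the energy-weighted mean frequency of scalogram column b (a
spectral-centroid time series); NTI(a) is the energy-weighted mean time of
row a (a temporal-centroid spectrum).  Eight statistics of each series —
mean, variance, slope, kurtosis, skewness, entropy, power, mode — form the
16-dimensional feature vector.

Statistic conventions (configurable via FeatureConventions):
  variance   population (divide by n)
  slope      OLS slope of the series against its natural axis
             (time in s for NSI, frequency in Hz for NTI)
  kurtosis   Pearson m4/m2^2 (not excess); 0 for a constant series
  skewness   m3/m2^(3/2); 0 for a constant series
  entropy    Shannon entropy in bits of a 32-bin equal-width histogram
  power      mean of squared values
  mode       midpoint of the most populated histogram bin (leftmost on ties)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .wavelet import Scalogram

__all__ = [
    "NsiSeries",
    "NtiSeries",
    "FeatureConventions",
    "FeatureVector",
    "FEATURE_NAMES",
    "compute_nsi",
    "compute_nti",
    "compute_features",
    "series_statistics",
]

#: Canonical feature order: the NSI block first, then the NTI block.
FEATURE_NAMES: tuple[str, ...] = (
    "mean_nsi", "variance_nsi", "slope_nsi", "kurtosis_nsi",
    "skewness_nsi", "entropy_nsi", "power_nsi", "mode_nsi",
    "mean_nti", "variance_nti", "slope_nti", "kurtosis_nti",
    "skewness_nti", "entropy_nti", "power_nti", "mode_nti",
)


@dataclass(frozen=True)
class NsiSeries:
    """Spectral centroid per time column, in Hz; NaN marks undefined."""

    values: np.ndarray
    times: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class NtiSeries:
    """Temporal centroid per scale row, in s; NaN marks undefined."""

    values: np.ndarray
    freqs: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def compute_nsi(S: Scalogram) -> NsiSeries:
    """NSI(b) = sum_a E(a,b) F(a) / sum_a E(a,b).

    Columns with zero total energy are undefined (NaN) and excluded from
    downstream statistics; an all-zero scalogram is rejected.
    """
    col_sum = S.E.sum(axis=0)
    if np.all(col_sum == 0):
        raise ValueError("degenerate scalogram: all columns have zero energy")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (S.grid.freqs @ S.E) / col_sum
    values = np.where(col_sum == 0, np.nan, values)
    return NsiSeries(values=values, times=S.grid.times.copy())


def compute_nti(S: Scalogram) -> NtiSeries:
    """NTI(a) = sum_b E(a,b) T(b) / sum_b E(a,b) — the row-wise mirror."""
    row_sum = S.E.sum(axis=1)
    if np.all(row_sum == 0):
        raise ValueError("degenerate scalogram: all rows have zero energy")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (S.E @ S.grid.times) / row_sum
    values = np.where(row_sum == 0, np.nan, values)
    return NtiSeries(values=values, freqs=S.grid.freqs.copy())


@dataclass(frozen=True)
class FeatureConventions:
    """Knobs for the statistic definitions; defaults give the stated set."""

    n_bins: int = 32
    population_variance: bool = True
    excess_kurtosis: bool = False


@dataclass(frozen=True)
class FeatureVector:
    """The 16 named scalogram statistics, NSI block then NTI block."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")

    def as_array(self, names: Optional[tuple[str, ...]] = None) -> np.ndarray:
        names = names or FEATURE_NAMES
        return np.array([self.values[n] for n in names], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def series_statistics(
    values: np.ndarray,
    axis: np.ndarray,
    conv: FeatureConventions = FeatureConventions(),
) -> dict[str, float]:
    """The eight statistics of one centroid series against its axis."""
    mask = ~np.isnan(values)
    v = values[mask]
    x = axis[mask]
    if v.size < 3:
        raise ValueError("need at least 3 defined series values")
    n = v.size
    mean = float(v.mean())
    dev = v - mean
    m2 = float(np.mean(dev**2))
    variance = m2 if conv.population_variance else m2 * n / (n - 1)

    xc = x - x.mean()
    denom = float(xc @ xc)
    slope = float(xc @ v) / denom if denom > 0 else 0.0

    if m2 == 0.0:
        warnings.warn(
            "zero-variance series: kurtosis and skewness set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        kurtosis = 0.0
        skewness = 0.0
    else:
        kurtosis = float(np.mean(dev**4)) / m2**2
        if conv.excess_kurtosis:
            kurtosis -= 3.0
        skewness = float(np.mean(dev**3)) / m2**1.5

    power = float(np.mean(v**2))

    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        entropy = 0.0
        mode = lo
    else:
        counts, edges = np.histogram(v, bins=conv.n_bins, range=(lo, hi))
        p = counts[counts > 0] / n
        entropy = float(-(p * np.log2(p)).sum())
        imax = int(np.argmax(counts))  # argmax returns the leftmost tie
        mode = float(0.5 * (edges[imax] + edges[imax + 1]))

    return {
        "mean": mean,
        "variance": variance,
        "slope": slope,
        "kurtosis": kurtosis,
        "skewness": skewness,
        "entropy": entropy,
        "power": power,
        "mode": mode,
    }


def compute_features(
    nsi: NsiSeries,
    nti: NtiSeries,
    conv: FeatureConventions = FeatureConventions(),
) -> FeatureVector:
    """Assemble the 16-feature vector from the two centroid series."""
    s_nsi = series_statistics(nsi.values, nsi.times, conv)
    s_nti = series_statistics(nti.values, nti.freqs, conv)
    values = {f"{k}_nsi": val for k, val in s_nsi.items()}
    values.update({f"{k}_nti": val for k, val in s_nti.items()})
    return FeatureVector(values=values)
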