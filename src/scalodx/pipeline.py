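"""Configuration and segment-to-feature plumbing shared by CLI and CV."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import (
    FEATURE_NAMES,
    FeatureConventions,
    compute_features,
    compute_nsi,
    compute_nti,
)
from .signal_io import Segment
from .wavelet import (
    GaborParams,
    NonlinearSpec,
    PseudoDiffSpec,
    ScaleGrid,
    compute_scalogram,
    default_scale_grid,
)

__all__ = ["PipelineConfig", "extract_features", "segment_features"]

#: The feature triple the decision stage operates on by default.
DEFAULT_DECISION_FEATURES: tuple[str, str, str] = (
    "mean_nsi",
    "variance_nsi",
    "mean_nti",
)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings; the defaults are the adopted operating point."""

    sigma: float = 1.0
    omega0: float = 2.0
    fmin_hz: float = 0.5
    fmax_hz: float = 32.0
    n_scales: int = 64
    operator: str = "inverse"  # L(a) = 1/a
    gamma: float = 1.0
    q: float = 0.25  # H = |.|^(1/4)
    n_bins: int = 32
    features: tuple[str, ...] = DEFAULT_DECISION_FEATURES  # or ("auto",)
    lambdas: tuple[float, ...] = (6.0, 1.0, 1.0)
    exponents: tuple[float, ...] = (1.0, 1.0, 1.0)
    cv_k: int = 4
    seed: int = 0

    def gabor_params(self) -> GaborParams:
        return GaborParams(sigma=self.sigma, omega0=self.omega0)

    def operator_spec(self) -> PseudoDiffSpec:
        return PseudoDiffSpec(form=self.operator, gamma=self.gamma)

    def nonlinear_spec(self) -> NonlinearSpec:
        return NonlinearSpec(q=self.q)

    def conventions(self) -> FeatureConventions:
        return FeatureConventions(n_bins=self.n_bins)

    def scale_grid(self, seg: Segment) -> ScaleGrid:
        return default_scale_grid(
            seg, fmin=self.fmin_hz, fmax=self.fmax_hz, n_scales=self.n_scales
        )

    def config_hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        kwargs = dict(doc)
        for key in ("features", "lambdas", "exponents"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def segment_features(
    seg: Segment, config: PipelineConfig = PipelineConfig()
) -> dict[str, float]:
    """All 16 scalogram statistics for one segment."""
    S = compute_scalogram(
        seg,
        grid=config.scale_grid(seg),
        params=config.gabor_params(),
        operator=config.operator_spec(),
        nonlinearity=config.nonlinear_spec(),
    )
    fv = compute_features(compute_nsi(S), compute_nti(S), config.conventions())
    return dict(fv.values)


def extract_features(
    segments: Sequence[Segment], config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Feature table: one row per segment, 16 feature columns + provenance."""
    rows = []
    for seg in segments:
        row = segment_features(seg, config)
        row["label"] = seg.label
        row["record_id"] = seg.record_id
        row["start_index"] = seg.start_index
        rows.append(row)
    cols = list(FEATURE_NAMES) + ["label", "record_id", "start_index"]
    return pd.DataFrame(rows, columns=cols)
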