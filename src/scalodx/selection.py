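"""Per-feature class-separability scoring with within/between-class scatter.

Each feature is scored independently by J = S_b / S_w where, for classes
D_i with priors P_i = n_i / N, class means mu_i and overall mean mu,

    S_w = sum_i sum_{x in D_i} w_i (x - mu_i)^2
    S_b = sum_i P_i (mu_i - mu)^2.

Two conventions for the within-class sample weight w_i are provided:
``literal`` uses w_i = P_i (each sample weighted by its class prior), and
``normalized`` uses w_i = 1/N (the standard Fisher form, under which the
total scatter decomposes exactly as S_t = S_w + S_b).  They coincide for
balanced classes.  The top-scoring features feed the decision stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = [
    "ClassedFeatureTable",
    "SeparabilityScores",
    "class_means",
    "scatter_scores",
    "select_top_k",
]


@dataclass(frozen=True)
class ClassedFeatureTable:
    """Feature matrix (N x D) with one class label per row."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        labels = np.asarray(self.labels)
        if X.ndim != 2 or X.shape[0] != labels.size:
            raise ValueError("X must be N x D with one label per row")
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match X columns")
        if np.unique(labels).size < 2:
            raise ValueError("need at least 2 classes")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label",
        feature_names: Optional[Sequence[str]] = None,
    ) -> "ClassedFeatureTable":
        names = tuple(feature_names) if feature_names else tuple(
            c for c in df.columns if c in FEATURE_NAMES
        )
        return cls(
            X=df[list(names)].to_numpy(float),
            labels=df[label_col].to_numpy(),
            feature_names=names,
        )

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def priors(self) -> dict:
        n = self.labels.size
        return {c: np.sum(self.labels == c) / n for c in self.classes}


@dataclass(frozen=True)
class SeparabilityScores:
    """Per-feature S_w, S_b and J = S_b/S_w (np.inf when S_w = 0)."""

    s_w: dict[str, float]
    s_b: dict[str, float]
    J: dict[str, float]
    convention: str
    feature_order: tuple[str, ...]

    @property
    def ranking(self) -> list[str]:
        """Features by J descending; ties broken by canonical table order."""
        order = {name: i for i, name in enumerate(self.feature_order)}
        return sorted(self.feature_order, key=lambda f: (-self.J[f], order[f]))

    def to_dataframe(self) -> pd.DataFrame:
        rank = {f: i + 1 for i, f in enumerate(self.ranking)}
        return pd.DataFrame(
            {
                "feature": list(self.feature_order),
                "S_w": [self.s_w[f] for f in self.feature_order],
                "S_b": [self.s_b[f] for f in self.feature_order],
                "J": [self.J[f] for f in self.feature_order],
                "rank": [rank[f] for f in self.feature_order],
            }
        )


def class_means(table: ClassedFeatureTable) -> tuple[dict, np.ndarray]:
    """Per-class mean vectors mu_i and the overall mean mu."""
    mus = {}
    for c in table.classes:
        rows = table.X[table.labels == c]
        if rows.size == 0:
            raise ValueError(f"empty class {c!r}")
        mus[c] = rows.mean(axis=0)
    return mus, table.X.mean(axis=0)


def scatter_scores(
    table: ClassedFeatureTable, convention: str = "literal"
) -> SeparabilityScores:
    """Score every feature by J = S_b / S_w under the chosen convention."""
    if convention not in ("literal", "normalized"):
        raise ValueError("convention must be 'literal' or 'normalized'")
    mus, mu = class_means(table)
    priors = table.priors
    N = table.labels.size

    D = len(table.feature_names)
    s_w = np.zeros(D)
    s_b = np.zeros(D)
    for c in table.classes:
        rows = table.X[table.labels == c]
        w = priors[c] if convention == "literal" else 1.0 / N
        s_w += w * ((rows - mus[c]) ** 2).sum(axis=0)
        s_b += priors[c] * (mus[c] - mu) ** 2

    if np.all(s_w == 0) and np.all(s_b == 0):
        raise ValueError("degenerate table: zero within- and between-class scatter")

    J = np.empty(D)
    for j in range(D):
        if s_w[j] == 0:
            if s_b[j] > 0:
                warnings.warn(
                    f"feature {table.feature_names[j]!r} has zero within-class "
                    "scatter; J set to +inf",
                    RuntimeWarning,
                    stacklevel=2,
                )
                J[j] = np.inf
            else:
                J[j] = 0.0
        else:
            J[j] = s_b[j] / s_w[j]

    names = table.feature_names
    return SeparabilityScores(
        s_w=dict(zip(names, s_w)),
        s_b=dict(zip(names, s_b)),
        J=dict(zip(names, J)),
        convention=convention,
        feature_order=names,
    )


def select_top_k(scores: SeparabilityScores, k: int = 3) -> list[str]:
    """The k highest-J features, canonical-order tie-break, J descending."""
    if k > len(scores.feature_order):
        raise ValueError(
            f"k={k} exceeds the {len(scores.feature_order)} available features"
        )
    return scores.ranking[:k]
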