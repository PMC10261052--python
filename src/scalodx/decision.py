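"""Open-neighborhood decision rule under a weighted non-Euclidean measure.

The dissimilarity between feature points x, y in R^D is

    rho(x, y) = sum_j lambda_j |x_j - y_j|^(p_j)          (diagonal form)

or, with a symmetric positive-definite matrix A and
w_j = |x_j - y_j|^(p_j / 2),

    rho(x, y) = w A w^T                                    (quadratic form),

which reduces to the diagonal form when A = diag(lambda).  rho is symmetric
and vanishes iff x = y but need not satisfy the triangle inequality; the
open balls {y : rho(x, y) < r} nevertheless generate a topology, and a test
point is assigned the label of the single training point contained in the
largest such ball — equivalently, of the rho-nearest training point.

The per-axis weights lambda act as axis scalings, so features are used on
their raw scales.  The operating point tuned for the shockable/non-shockable
problem on (mean NSI, variance NSI, mean NTI) is lambda = (6, 1, 1),
p = (1, 1, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MetricSpec",
    "TrainingSet",
    "Prediction",
    "rho",
    "classify",
    "classify_batch",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class MetricSpec:
    """Weights lambda_j > 0, exponents p_j > 0, optional SPD matrix A."""

    lambdas: tuple[float, ...] = (6.0, 1.0, 1.0)
    exponents: tuple[float, ...] = (1.0, 1.0, 1.0)
    A: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        lambdas = tuple(float(v) for v in self.lambdas)
        exponents = tuple(float(v) for v in self.exponents)
        if len(lambdas) != len(exponents):
            raise ValueError("lambdas and exponents must have equal length")
        if any(v <= 0 for v in lambdas) or any(v <= 0 for v in exponents):
            raise ValueError("all lambda_j and p_j must be positive")
        object.__setattr__(self, "lambdas", lambdas)
        object.__setattr__(self, "exponents", exponents)
        if self.A is not None:
            A = np.asarray(self.A, dtype=float)
            if A.shape != (len(lambdas), len(lambdas)):
                raise ValueError("A must be D x D")
            if not np.allclose(A, A.T):
                raise ValueError("A must be symmetric")
            if np.any(np.linalg.eigvalsh(A) <= 0):
                raise ValueError("A must be positive definite")
            object.__setattr__(self, "A", A)

    @property
    def dim(self) -> int:
        return len(self.lambdas)


@dataclass(frozen=True)
class TrainingSet:
    """Reference feature points with class labels."""

    points: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        labels = np.asarray(self.labels)
        if points.ndim != 2 or points.shape[0] == 0:
            raise ValueError("points must be a non-empty M x D array")
        if labels.shape != (points.shape[0],):
            raise ValueError("one label per training point required")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "labels", labels)

    @property
    def class_sizes(self) -> dict:
        cls, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(cls.tolist(), counts.tolist()))


@dataclass(frozen=True)
class Prediction:
    label: object
    nearest_distance: float
    nearest_index: int
    tie_count: int = 1


def rho(x: Sequence[float], y: Sequence[float], spec: MetricSpec) -> float:
    """Evaluate the dissimilarity between two points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.shape != (spec.dim,):
        raise ValueError(
            f"points must both have dimension {spec.dim}, got {x.shape}, {y.shape}"
        )
    d = np.abs(x - y)
    if spec.A is None:
        return float(np.dot(spec.lambdas, d ** np.asarray(spec.exponents)))
    w = d ** (np.asarray(spec.exponents) / 2.0)
    return float(w @ spec.A @ w)


def _rho_to_all(x: np.ndarray, points: np.ndarray, spec: MetricSpec) -> np.ndarray:
    d = np.abs(points - x)
    p = np.asarray(spec.exponents)
    if spec.A is None:
        return d**p @ np.asarray(spec.lambdas)
    w = d ** (p / 2.0)
    return np.einsum("ij,jk,ik->i", w, spec.A, w)


def classify(
    x: Sequence[float], train: TrainingSet, spec: MetricSpec
) -> Prediction:
    """Label of the rho-nearest training point (largest open ball holding one).

    Ties at the exact minimum are resolved deterministically: majority label
    among the tied points, then larger training-class size, then
    lexicographic label order.
    """
    x = np.asarray(x, dtype=float)
    dists = _rho_to_all(x, train.points, spec)
    dmin = dists.min()
    tied = np.flatnonzero(dists == dmin)
    if tied.size == 1:
        idx = int(tied[0])
        return Prediction(train.labels[idx], float(dmin), idx, 1)
    tied_labels = train.labels[tied]
    cls, counts = np.unique(tied_labels, return_counts=True)
    sizes = train.class_sizes
    # majority among ties -> larger class -> lexicographically first label
    order = sorted(
        range(cls.size),
        key=lambda i: (-counts[i], -sizes[cls[i].item()], str(cls[i])),
    )
    winner = cls[order[0]]
    idx = int(tied[tied_labels == winner][0])
    return Prediction(train.labels[idx], float(dmin), idx, int(tied.size))


def classify_batch(
    X: np.ndarray, train: TrainingSet, spec: MetricSpec
) -> list[Prediction]:
    """Elementwise :func:`classify`, order preserved."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return []
    return [classify(x, train, spec) for x in np.atleast_2d(X)]


def save_model(path: str, train: TrainingSet, spec: MetricSpec) -> None:
    """Persist training points, labels, and the metric spec as JSON."""
    doc = {
        "points": train.points.tolist(),
        "labels": [str(l) for l in train.labels],
        "lambdas": list(spec.lambdas),
        "exponents": list(spec.exponents),
        "A": spec.A.tolist() if spec.A is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str) -> tuple[TrainingSet, MetricSpec]:
    with open(path) as fh:
        doc = json.load(fh)
    train = TrainingSet(
        points=np.asarray(doc["points"], dtype=float),
        labels=np.asarray(doc["labels"]),
    )
    spec = MetricSpec(
        lambdas=tuple(doc["lambdas"]),
        exponents=tuple(doc["exponents"]),
        A=np.asarray(doc["A"]) if doc.get("A") is not None else None,
    )
    return train, spec
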