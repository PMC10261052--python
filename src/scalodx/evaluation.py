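"""Stratified cross-validation and multi-class performance metrics.

Confusion matrices follow the orientation rows = predicted class,
columns = actual class.  Per-class precision, recall, F1 and one-vs-rest
accuracy are reported alongside macro averages (means of per-class values;
macro-F1 is the mean of per-class F1, not the harmonic mean of macro-P and
macro-R) and micro averages (pooled TP/FP/FN, which for single-label
prediction all equal the overall accuracy).

Two clinically motivated binary collapses of the four-class problem are
provided: normal-vs-abnormal (SR against the rest) and, restricted to
abnormal samples, PEA-vs-shockable (VF/VT).  In the latter an SR prediction
on an abnormal sample counts as non-shock advice — the conservative
reading, configurable via ``sr_prediction_counts_as``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decision import MetricSpec, TrainingSet, classify_batch
from .pipeline import PipelineConfig, extract_features
from .selection import ClassedFeatureTable, scatter_scores, select_top_k
from .signal_io import Segment

__all__ = [
    "FoldPlan",
    "ConfusionMatrix",
    "MetricsReport",
    "EvalReport",
    "stratified_kfold",
    "confusion",
    "metrics_from_confusion",
    "binary_scheme",
    "run_cv",
]

SHOCKABLE = frozenset({"VF", "VT"})


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: np.ndarray  # fold index per sample
    seed: int


def stratified_kfold(labels: Sequence, k: int = 4, seed: int = 0) -> FoldPlan:
    """Seeded stratified partition; per class, fold sizes differ by <= 1."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.full(labels.size, -1, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise ValueError(f"class {c!r} has {idx.size} samples, fewer than k={k}")
        idx = rng.permutation(idx)
        assignments[idx] = np.arange(idx.size) % k
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = predicted, columns = actual."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if counts.shape != (c, c) or np.any(counts < 0):
            raise ValueError("confusion counts must be a nonnegative c x c matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class sets differ")
        return ConfusionMatrix(self.counts + other.counts, self.classes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"pred_{c}" for c in self.classes],
            columns=[f"actual_{c}" for c in self.classes],
        )


def confusion(
    preds: Sequence, actuals: Sequence, classes: Sequence[str]
) -> ConfusionMatrix:
    preds = np.asarray(preds)
    actuals = np.asarray(actuals)
    if preds.size != actuals.size:
        raise ValueError("preds and actuals must have equal length")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, a in zip(preds, actuals):
        if str(p) not in index or str(a) not in index:
            raise ValueError(f"label outside declared classes: {p!r}/{a!r}")
        counts[index[str(p)], index[str(a)]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[str, dict[str, float]]  # precision/recall/f1/accuracy
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "micro": {
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "f1": self.micro_f1,
            },
            "accuracy": self.accuracy,
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"0/0 {what} defined as 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class P/R/F1/accuracy plus macro and micro averages."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts
    total = cm.total
    per_class: dict[str, dict[str, float]] = {}
    tps = fps = fns = 0
    for i, c in enumerate(cm.classes):
        tp = int(counts[i, i])
        fp = int(counts[i, :].sum()) - tp  # predicted c, actually other
        fn = int(counts[:, i].sum()) - tp  # actually c, predicted other
        tn = total - tp - fp - fn
        p = _safe_div(tp, tp + fp, "precision")
        r = _safe_div(tp, tp + fn, "recall")
        f1 = _safe_div(2 * p * r, p + r, "F1")
        per_class[c] = {
            "precision": p,
            "recall": r,
            "f1": f1,
            "accuracy": (tp + tn) / total,
        }
        tps, fps, fns = tps + tp, fps + fp, fns + fn
    macro_p = float(np.mean([m["precision"] for m in per_class.values()]))
    macro_r = float(np.mean([m["recall"] for m in per_class.values()]))
    macro_f1 = float(np.mean([m["f1"] for m in per_class.values()]))
    micro_p = _safe_div(tps, tps + fps, "micro precision")
    micro_r = _safe_div(tps, tps + fns, "micro recall")
    micro_f1 = _safe_div(2 * micro_p * micro_r, micro_p + micro_r, "micro F1")
    accuracy = float(np.trace(counts)) / total
    return MetricsReport(
        per_class=per_class,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f1,
        micro_precision=micro_p,
        micro_recall=micro_r,
        micro_f1=micro_f1,
        accuracy=accuracy,
    )


def binary_scheme(
    preds: Sequence,
    actuals: Sequence,
    scheme: str,
    sr_prediction_counts_as: str = "non_shock",
) -> MetricsReport:
    """Collapse four-class predictions into one of the two binary schemes.

    ``normal_vs_abnormal``: SR -> negative, {PEA, VF, VT} -> positive, on
    all samples.  ``pea_vs_shockable``: restricted to samples whose actual
    class is abnormal; predictions in {VF, VT} -> shock, PEA -> non-shock,
    and an SR prediction counts per ``sr_prediction_counts_as``
    ("non_shock" or "shock").
    """
    preds = np.asarray([str(p) for p in preds])
    actuals = np.asarray([str(a) for a in actuals])
    if scheme == "normal_vs_abnormal":
        collapse = lambda l: "normal" if l == "SR" else "abnormal"
        p2 = np.array([collapse(l) for l in preds])
        a2 = np.array([collapse(l) for l in actuals])
        classes = ("abnormal", "normal")
    elif scheme == "pea_vs_shockable":
        keep = np.array([a != "SR" for a in actuals])
        sr_as = "shock" if sr_prediction_counts_as == "shock" else "non_shock"

        def collapse(l: str) -> str:
            if l in SHOCKABLE:
                return "shock"
            if l == "SR":
                return sr_as
            return "non_shock"

        p2 = np.array([collapse(l) for l in preds[keep]])
        a2 = np.array([collapse(l) for l in actuals[keep]])
        classes = ("shock", "non_shock")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return metrics_from_confusion(confusion(p2, a2, classes))


@dataclass(frozen=True)
class EvalReport:
    """Per-fold and pooled results of one cross-validated run."""

    fold_confusions: list[ConfusionMatrix]
    fold_metrics: list[MetricsReport]
    pooled_confusion: ConfusionMatrix
    pooled_metrics: MetricsReport
    normal_vs_abnormal: MetricsReport
    pea_vs_shockable: MetricsReport
    selected_features: tuple[str, ...]
    config_hash: str

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "selected_features": list(self.selected_features),
            "folds": [
                {
                    "confusion": cm.counts.tolist(),
                    "classes": list(cm.classes),
                    "metrics": m.to_dict(),
                }
                for cm, m in zip(self.fold_confusions, self.fold_metrics)
            ],
            "pooled": {
                "confusion": self.pooled_confusion.counts.tolist(),
                "classes": list(self.pooled_confusion.classes),
                "metrics": self.pooled_metrics.to_dict(),
            },
            "normal_vs_abnormal": self.normal_vs_abnormal.to_dict(),
            "pea_vs_shockable": self.pea_vs_shockable.to_dict(),
        }


def run_cv(
    segments: Sequence[Segment],
    config: PipelineConfig = PipelineConfig(),
    feature_table: Optional[pd.DataFrame] = None,
) -> EvalReport:
    """Cross-validated evaluation of the full pipeline on labeled segments.

    Features are extracted once (or supplied precomputed); the decision
    stage is trained and tested per stratified fold.  With
    ``config.features == ('auto',)`` the top-3 scatter-score features are
    re-selected on each training fold; otherwise the configured triple is
    used throughout.
    """
    if feature_table is None:
        feature_table = extract_features(segments, config)
    labels = feature_table["label"].to_numpy(str)
    if any(l in (None, "None", "nan") for l in labels):
        raise ValueError("all segments must be labeled for cross-validation")
    classes = tuple(sorted(set(labels)))
    plan = stratified_kfold(labels, k=config.cv_k, seed=config.seed)

    auto = tuple(config.features) == ("auto",)
    spec = MetricSpec(lambdas=config.lambdas, exponents=config.exponents)

    fold_cms: list[ConfusionMatrix] = []
    fold_metrics: list[MetricsReport] = []
    all_preds = np.empty(labels.size, dtype=object)
    selected: tuple[str, ...] = tuple(config.features)
    for fold in range(plan.k):
        test = plan.assignments == fold
        train = ~test
        if auto:
            table = ClassedFeatureTable.from_dataframe(feature_table.loc[train])
            selected = tuple(select_top_k(scatter_scores(table), k=spec.dim))
        feats = list(selected)
        Xtr = feature_table.loc[train, feats].to_numpy(float)
        Xte = feature_table.loc[test, feats].to_numpy(float)
        tset = TrainingSet(points=Xtr, labels=labels[train])
        preds = np.array([p.label for p in classify_batch(Xte, tset, spec)])
        all_preds[test] = preds
        cm = confusion(preds, labels[test], classes)
        fold_cms.append(cm)
        fold_metrics.append(metrics_from_confusion(cm))

    pooled_cm = fold_cms[0]
    for cm in fold_cms[1:]:
        pooled_cm = pooled_cm + cm
    return EvalReport(
        fold_confusions=fold_cms,
        fold_metrics=fold_metrics,
        pooled_confusion=pooled_cm,
        pooled_metrics=metrics_from_confusion(pooled_cm),
        normal_vs_abnormal=binary_scheme(all_preds, labels, "normal_vs_abnormal"),
        pea_vs_shockable=binary_scheme(all_preds, labels, "pea_vs_shockable"),
        selected_features=selected,
        config_hash=config.config_hash(),
    )
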