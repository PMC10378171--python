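"""Classifier training and the confusion-matrix evaluation protocol.

Four classifier families are supported — a one-hidden-layer neural network
(ann), an impurity-based decision tree (dt), AdaBoost over stumps
(adaboost) and an RBF-kernel SVM (svm) — all delegated to scikit-learn;
they are standard components, not the method under study. Metrics are the
clinical four: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, and AUC (trapezoidal ROC area, equal to the Mann-Whitney
probability with ties counted half). The positive class is target = 1
(disease), so sensitivity is the disease detection rate.

Two evaluation protocols are available: a stratified 70/30 holdout and
stratified k-fold cross-validation (default k = 10) with macro-averaged
per-fold metrics plus the pooled confusion matrix.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

CLASSIFIER_IDS = ("ann", "dt", "adaboost", "svm")

#: marker for metrics whose denominator is empty
UNDEFINED = float("nan")


def _load_defaults() -> dict[str, dict[str, Any]]:
    text = resources.files("jsofs").joinpath("classifier_defaults.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULT_HYPER = _load_defaults()


# ---------------------------------------------------------------------------
# Split specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Evaluation protocol: stratified 70/30 holdout or k-fold CV."""

    mode: str = "holdout"          # holdout | kfold
    train_fraction: float = 0.70
    k: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("holdout", "kfold"):
            raise ValueError("mode must be 'holdout' or 'kfold'")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be at least 2")


def iter_splits(split: SplitSpec, labels: np.ndarray):
    """Yield (train_idx, test_idx) pairs for the chosen protocol."""
    idx = np.arange(len(labels))
    if split.mode == "holdout":
        strat = labels if split.stratified else None
        tr, te = train_test_split(idx, train_size=split.train_fraction,
                                  random_state=split.seed, stratify=strat)
        yield tr, te
    else:
        cls = StratifiedKFold if split.stratified else KFold
        folds = cls(n_splits=split.k, shuffle=True, random_state=split.seed)
        yield from folds.split(idx, labels)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def make_model(classifier_id: str, hyper: Mapping[str, Any] | None = None):
    """Build a trainable model for one of {ann, dt, adaboost, svm}.

    The returned estimator exposes ``fit`` and hard predictions via
    ``predict``; continuous scores for ROC come from ``predict_proba``
    (ann, dt, adaboost) or ``decision_function`` (svm) — see
    :func:`predict_scores`. Defaults are pinned in
    ``classifier_defaults.yaml``; ``hyper`` overrides individual entries.
    """
    if classifier_id not in CLASSIFIER_IDS:
        raise ValueError(
            f"unknown classifier {classifier_id!r}; valid ids: {CLASSIFIER_IDS}"
        )
    params = dict(_DEFAULT_HYPER[classifier_id])
    if hyper:
        params.update(hyper)
    if classifier_id == "ann":
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        return MLPClassifier(**params)
    if classifier_id == "dt":
        return DecisionTreeClassifier(**params)
    if classifier_id == "adaboost":
        depth = params.pop("max_depth", 1)
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=depth), **params
        )
    params.pop("random_state", None)   # RBF SVC decision function is deterministic
    return SVC(**params)


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores for ROC: class-1 probability, decision function,
    or — for score-less stubs — the hard predictions themselves."""
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1]
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X))
    return np.asarray(model.predict(X), dtype=float)


def _clone(model):
    try:
        return clone(model)
    except TypeError:
        return copy.deepcopy(model)


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with target = 1 (disease) as the positive class."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError(
            f"labels (n={y.size}) and predictions (n={p.size}) differ in length"
        )
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN); NaN when no positives were evaluated."""
    d = cm.tp + cm.fn
    return cm.tp / d if d else UNDEFINED


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP); NaN when no negatives were evaluated."""
    d = cm.tn + cm.fp
    return cm.tn / d if d else UNDEFINED


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + TN + FP + FN); NaN on an empty matrix."""
    return (cm.tp + cm.tn) / cm.total if cm.total else UNDEFINED


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (ties counted half); NaN if one class absent."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        return UNDEFINED
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """The four headline metrics, optionally with a per-fold breakdown."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    pooled: ConfusionMatrix
    per_fold: list[dict[str, float]] | None = None

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "confusion": {"tp": self.pooled.tp, "fp": self.pooled.fp,
                          "tn": self.pooled.tn, "fn": self.pooled.fn},
        }
        if self.per_fold is not None:
            out["per_fold"] = self.per_fold
        return out


def _check_both_classes(y: np.ndarray, what: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{what} contains a single class; cannot train/evaluate")


def evaluate(model, data, mask=None, split: SplitSpec | None = None) -> MetricsReport:
    """Train and evaluate a model under the chosen protocol.

    ``data`` is a :class:`~jsofs.data.DatasetTable`; ``mask`` an optional
    :class:`~jsofs.selection.FeatureMask` restricting the columns (full
    feature set when None). Holdout: metrics on the held-out 30%. K-fold:
    per-fold metrics from fold-level confusion matrices, macro-averaged,
    reported alongside the pooled matrix.
    """
    if split is None:
        split = SplitSpec()
    X = data.features if mask is None else data.features[:, mask.included]
    y = np.asarray(data.labels).astype(int)

    fold_metrics: list[dict[str, float]] = []
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for f, (tr, te) in enumerate(iter_splits(split, y)):
        try:
            _check_both_classes(y[tr], "training partition")
            _check_both_classes(y[te], "test partition")
        except ValueError as exc:
            raise ValueError(f"fold {f}: {exc}") from None
        m = _clone(model)
        m.fit(X[tr], y[tr])
        pred = m.predict(X[te])
        scores = predict_scores(m, X[te])
        cm = confusion(y[te], pred)
        pooled = pooled + cm
        fold_metrics.append({
            "fold": f,
            "sensitivity": sensitivity(cm),
            "specificity": specificity(cm),
            "accuracy": accuracy(cm),
            "auc": auc(y[te], scores),
        })

    if split.mode == "holdout":
        fm = fold_metrics[0]
        return MetricsReport(fm["sensitivity"], fm["specificity"],
                             fm["accuracy"], fm["auc"], pooled)
    agg = {k: float(np.mean([fm[k] for fm in fold_metrics]))
           for k in ("sensitivity", "specificity", "accuracy", "auc")}
    return MetricsReport(agg["sensitivity"], agg["specificity"],
                         agg["accuracy"], agg["auc"], pooled,
                         per_fold=fold_metrics)


def metrics_table(reports: Mapping[str, MetricsReport]) -> pd.DataFrame:
    """Tables-shaped frame: rows = model, metric columns in percent (2 dp)."""
    rows = {
        name: {
            "Sensitivity (%)": round(100 * r.sensitivity, 2),
            "Specificity (%)": round(100 * r.specificity, 2),
            "Accuracy (%)": round(100 * r.accuracy, 2),
            "AUC (%)": round(100 * r.auc, 2),
        }
        for name, r in reports.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "Model"
    return df
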