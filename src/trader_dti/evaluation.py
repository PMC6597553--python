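"""Cross-validation and classification metrics.

Reports accuracy, sensitivity, specificity and precision as percentages,
ROC and precision-recall curves with trapezoidal AUC, and supports the
positives-only ("one-class") convention where only true positives and false
negatives exist and accuracy reduces to TP / (TP + FN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold

from .ann import MLPSpec
from .pipeline import TrainedModel, feature_columns, train_anntr
from .trader import TraderConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "metrics",
    "kfold_split",
    "Curve",
    "roc_curve",
    "pr_curve",
    "CVResult",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, labels, predicted) -> "ConfusionCounts":
        y = np.asarray(labels).astype(int)
        p = np.asarray(predicted).astype(int)
        if y.shape != p.shape:
            raise ValueError("labels and predictions must align")
        return cls(
            tp=int(np.sum((y == 1) & (p == 1))),
            fp=int(np.sum((y == 0) & (p == 1))),
            tn=int(np.sum((y == 0) & (p == 0))),
            fn=int(np.sum((y == 1) & (p == 0))),
        )


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def metrics(counts: ConfusionCounts) -> dict:
    """ACC, SEN, SPC, PRE as percentages; a metric whose denominator is zero
    is reported as None (undefined), never silently 0."""
    if counts.total == 0:
        raise ValueError("no evaluated rows")
    return {
        "ACC": _ratio(counts.tp + counts.tn, counts.total),
        "SEN": _ratio(counts.tp, counts.tp + counts.fn),
        "SPC": _ratio(counts.tn, counts.tn + counts.fp),
        "PRE": _ratio(counts.tp, counts.tp + counts.fp),
    }


def kfold_split(dataset: pd.DataFrame, k: int, seed: int, label_col: str = "label"):
    """Stratified, seeded, disjoint and exhaustive folds (sizes differ by at
    most one); returns a list of row-position arrays."""
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds dataset size {n}")
    y = dataset[label_col].to_numpy()
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n), y)]


@dataclass(frozen=True)
class Curve:
    """Ordered curve points plus the trapezoidal area under them."""

    x: np.ndarray
    y: np.ndarray
    auc: float


def roc_curve(scores, labels) -> Curve:
    """ROC curve (FPR vs TPR) from a threshold sweep with ties grouped;
    requires both classes."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC curve requires both classes to be present")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    return Curve(fpr, tpr, float(np.trapezoid(tpr, fpr)))


def pr_curve(scores, labels) -> Curve:
    """Precision-recall curve (recall ascending) with trapezoidal AUC;
    requires at least one positive."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if np.sum(y == 1) == 0:
        raise ValueError("PR curve requires at least one positive")
    precision, recall, _ = _skm.precision_recall_curve(y, s)
    recall, precision = recall[::-1], precision[::-1]  # recall ascending
    return Curve(recall, precision, float(np.trapezoid(precision, recall)))


@dataclass
class CVResult:
    fold_metrics: list
    mean_metrics: dict
    roc: Curve | None
    pr: Curve | None
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    fold_models: list


def _mean_of(fold_metrics: list, key: str) -> float | None:
    vals = [m[key] for m in fold_metrics if m[key] is not None]
    return float(np.mean(vals)) if vals else None


def cross_validate(
    dataset: pd.DataFrame,
    spec: MLPSpec | None = None,
    trader_cfg: TraderConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """k-fold cross-validation of the Trader-trained network.

    Each fold trains on the other k-1 folds (optimizer seed offset by the
    fold index) and is evaluated on the held-out rows at the network's
    threshold.  Reported metrics are the arithmetic mean of the fold metrics;
    the curves pool the held-out scores of all folds and are omitted (None)
    when the pooled labels contain a single class.
    """
    spec = spec or MLPSpec()
    folds = kfold_split(dataset, k, seed)
    fold_metrics = []
    fold_models = []
    pooled_scores = []
    pooled_labels = []
    cols = feature_columns(dataset)
    for i, test_idx in enumerate(folds):
        mask = np.zeros(len(dataset), dtype=bool)
        mask[test_idx] = True
        train_df = dataset.iloc[~mask]
        test_df = dataset.iloc[mask]
        cfg = trader_cfg
        if cfg is not None:
            cfg = replace(cfg, seed=cfg.seed + i)
        try:
            model = train_anntr(train_df, spec, cfg)
        except Exception as err:
            raise RuntimeError(f"training failed on fold {i}: {err}") from err
        scores = model.scores(test_df[cols].to_numpy(dtype=float))
        y = test_df["label"].to_numpy(dtype=int)
        predicted = (scores >= spec.threshold).astype(int)
        fold_metrics.append(metrics(ConfusionCounts.from_predictions(y, predicted)))
        fold_models.append(model)
        pooled_scores.append(scores)
        pooled_labels.append(y)
    pooled_scores = np.concatenate(pooled_scores)
    pooled_labels = np.concatenate(pooled_labels)
    mean_metrics = {key: _mean_of(fold_metrics, key) for key in ("ACC", "SEN", "SPC", "PRE")}
    both_classes = len(np.unique(pooled_labels)) == 2
    roc = roc_curve(pooled_scores, pooled_labels) if both_classes else None
    pr = pr_curve(pooled_scores, pooled_labels) if np.any(pooled_labels == 1) else None
    return CVResult(
        fold_metrics, mean_metrics, roc, pr, pooled_scores, pooled_labels, fold_models
    )
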