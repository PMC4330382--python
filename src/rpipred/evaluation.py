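"""Performance measures and 10-fold cross-validation.

Metrics follow the standard confusion-matrix definitions, with accuracy on
a 0-100 scale:

    Precision = tp / (tp + fp)
    Recall    = tp / (tp + fn)
    F-measure = 2 * Precision * Recall / (Precision + Recall)
    Accuracy  = (tp + tn) / (tp + fp + fn + tn) * 100

Ratios with a zero denominator are reported as *undefined* (None), never
silently as 0. AUC is the rank-based (Mann-Whitney) statistic with tied
scores counted 1/2. Cross-validation uses seeded stratified folds; the
headline report pools out-of-fold confusion counts and scores
(micro-average), with a per-fold breakdown alongside since a plain
"average over folds" is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classifier import SVMParams, predict, train

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "compute_metrics",
    "roc_auc",
    "kfold_cv",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class MetricsReport:
    """Precision/recall/F-score in [0,1], accuracy in [0,100], AUC in [0,1].

    A None field means the corresponding ratio was undefined (zero
    denominator) or not computed.
    """

    precision: float | None
    recall: float | None
    fscore: float | None
    accuracy: float
    auc: float | None = None
    counts: ConfusionCounts | None = None
    per_fold: list["MetricsReport"] = field(default_factory=list)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate the four confusion-matrix measures exactly."""
    if counts.total == 0:
        raise ValueError("no evaluated pairs")
    pre = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    if pre is not None and rec is not None and pre + rec > 0:
        fsc = 2 * pre * rec / (pre + rec)
    else:
        fsc = None
    acc = (counts.tp + counts.tn) / counts.total * 100.0
    return MetricsReport(precision=pre, recall=rec, fscore=fsc, accuracy=acc, counts=counts)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(score+ > score-) with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks on ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    params: SVMParams | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the SVM.

    Each of the k near-equal folds is held out once; confusion counts are
    pooled across folds and AUC is computed over the pooled out-of-fold
    decision scores. ``per_fold`` carries the fold-level breakdown.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(y) < k:
        raise ValueError(f"need at least k={k} samples, got {len(y)}")
    params = params or SVMParams()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = ConfusionCounts()
    oof_scores = np.empty(len(y))
    per_fold: list[MetricsReport] = []
    for train_idx, test_idx in skf.split(X, y):
        model = train(X[train_idx], y[train_idx], params)
        labels, scores = predict(model, X[test_idx])
        oof_scores[test_idx] = scores
        fold_counts = ConfusionCounts.from_predictions(y[test_idx], labels)
        pooled = pooled + fold_counts
        per_fold.append(compute_metrics(fold_counts))
    report = compute_metrics(pooled)
    report.auc = roc_auc(oof_scores, y)
    report.per_fold = per_fold
    return report
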