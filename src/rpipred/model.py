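"""Model/Results front end over the pair classifier.

`RpiModel` holds the encoded training data and hyperparameters; `fit()`
returns an `RpiResults` carrying the trained SVM, training diagnostics and,
optionally, cross-validation metrics, with a `summary()` table in the style
of the usual statistical-modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import SVMParams, TrainedModel, load_model, predict, save_model, train
from .evaluation import ConfusionCounts, MetricsReport, compute_metrics, kfold_cv, roc_auc
from .fixtures import encode_pair_table

__all__ = ["RpiModel", "RpiResults"]


class RpiModel:
    """An RNA-protein interaction classifier specification bound to data.

    Parameters
    ----------
    X : (n, 132) array of pair feature vectors.
    y : binary labels, 1 = interacting.
    params : SVM hyperparameters; defaults are the tuned polynomial-kernel
        settings (C=1000, gamma=1, coef0=1, degree=4).
    pair_ids : optional row identifiers, carried into prediction tables.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        params: SVMParams | None = None,
        pair_ids: list[str] | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("X and y lengths differ")
        self.params = params or SVMParams()
        self.pair_ids = list(pair_ids) if pair_ids is not None else None

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, params: SVMParams | None = None
    ) -> "RpiModel":
        """Build from a pair table with columns protein_seq, pb, rna_seq,
        rss, label (and optionally pair_id), encoding rows on the fly."""
        X, y = encode_pair_table(table)
        ids = table["pair_id"].tolist() if "pair_id" in table.columns else None
        return cls(X, y, params=params, pair_ids=ids)

    def fit(self) -> "RpiResults":
        trained = train(self.X, self.y, self.params)
        labels, scores = predict(trained, self.X)
        counts = ConfusionCounts.from_predictions(self.y, labels)
        train_metrics = compute_metrics(counts)
        if len(set(self.y)) == 2:
            train_metrics.auc = roc_auc(scores, self.y)
        return RpiResults(model=self, trained=trained, train_metrics=train_metrics)

    def cross_validate(self, k: int = 10, seed: int = 0) -> MetricsReport:
        """Stratified k-fold cross-validation at this model's parameters."""
        return kfold_cv(self.X, self.y, k=k, seed=seed, params=self.params)


@dataclass
class RpiResults:
    """Fitted classifier with diagnostics."""

    model: RpiModel
    trained: TrainedModel
    train_metrics: MetricsReport
    cv_metrics: MetricsReport | None = field(default=None)

    def predict(
        self, X: np.ndarray, pair_ids: list[str] | None = None
    ) -> pd.DataFrame:
        """Score new pair vectors; returns a table with decision scores and
        hard labels (positive iff score > 0)."""
        labels, scores = predict(self.trained, np.asarray(X, dtype=float))
        ids = pair_ids if pair_ids is not None else [f"pair{i}" for i in range(len(labels))]
        return pd.DataFrame(
            {"pair_id": ids, "decision_score": scores, "predicted_label": labels}
        )

    def cross_validate(self, k: int = 10, seed: int = 0) -> MetricsReport:
        self.cv_metrics = self.model.cross_validate(k=k, seed=seed)
        return self.cv_metrics

    def save(self, path: str | Path) -> None:
        save_model(self.trained, path)

    @staticmethod
    def load(path: str | Path) -> TrainedModel:
        return load_model(path)

    def summary(self) -> str:
        p = self.trained.params
        n = len(self.model.y)
        n_pos = int(self.model.y.sum())
        lines = [
            "        RNA-Protein Interaction SVM Results",
            "=" * 52,
            f"No. observations:   {n:>8d}    Positives: {n_pos:>8d}",
            f"Features:           {self.trained.n_features:>8d}    Negatives: {n - n_pos:>8d}",
            f"Kernel:           polynomial    Support vecs: {int(self.trained.svc.n_support_.sum()):>5d}",
            f"C: {p.C:<10g} gamma: {p.gamma:<6g} coef0: {p.coef0:<6g} degree: {p.degree}",
            "-" * 52,
        ]

        def fmt(v, scale1=False):
            return "   undef" if v is None else f"{v:8.3f}"

        for name, m in [("Training", self.train_metrics), ("10-fold CV", self.cv_metrics)]:
            if m is None:
                continue
            lines.append(
                f"{name:<12s} ACC {m.accuracy:6.1f}  PRE {fmt(m.precision)}  "
                f"REC {fmt(m.recall)}  FSC {fmt(m.fscore)}  AUC {fmt(m.auc)}"
            )
        lines.append("=" * 52)
        return "\n".join(lines)
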