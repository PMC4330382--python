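"""Polynomial-kernel SVM over 132-dimensional pair vectors.

The classifier is a soft-margin SVM with the polynomial kernel
K(u, v) = (gamma <u, v> + coef0)^degree and the tuned hyperparameters
C = 1000, gamma = 1, coef0 = 1, degree = 4. Features are already
frequencies in [0, 1], so no further scaling is applied. Decision scores
(signed distance surrogate from the separating surface) drive both the
hard label (positive iff score > 0; ties break negative) and ROC ranking.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .features import N_FEATURES, layout_fingerprint

__all__ = [
    "SVMParams",
    "TrainedModel",
    "polynomial_kernel",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SVMParams:
    """Polynomial-kernel SVM hyperparameters (defaults are the tuned values)."""

    C: float = 1000.0
    gamma: float = 1.0
    coef0: float = 1.0
    degree: int = 4
    class_weight: str | dict | None = None  # imbalance weighting off by default

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0 or self.degree < 1:
            raise ValueError("require C > 0, gamma > 0, degree >= 1")


def polynomial_kernel(u: np.ndarray, v: np.ndarray, params: SVMParams | None = None) -> float:
    """(gamma <u, v> + coef0)^degree."""
    params = params or SVMParams()
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    return float((params.gamma * np.dot(u, v) + params.coef0) ** params.degree)


@dataclass
class TrainedModel:
    params: SVMParams
    svc: SVC
    fingerprint: str = field(default_factory=layout_fingerprint)
    n_features: int = N_FEATURES


def train(X: np.ndarray, y: np.ndarray, params: SVMParams | None = None) -> TrainedModel:
    """Fit the SVM on an (n, 132) matrix and binary labels (1 = interacting).

    Deterministic given input order: the dual solver needs no random
    initialization and probability calibration is not used.
    """
    params = params or SVMParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    svc = SVC(
        kernel="poly",
        C=params.C,
        gamma=params.gamma,
        coef0=params.coef0,
        degree=params.degree,
        class_weight=params.class_weight,
        shrinking=True,
    )
    svc.fit(X, y)
    return TrainedModel(params=params, svc=svc, n_features=X.shape[1])


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, decision scores) for new pair vectors.

    Refuses feature matrices whose layout fingerprint or width does not match
    the training layout. Label is 1 iff score > 0 (a tied score of exactly
    zero is called negative).
    """
    if model.fingerprint != layout_fingerprint() and model.n_features == N_FEATURES:
        raise ValueError(
            "feature-layout fingerprint mismatch: model was trained under a "
            "different feature index order"
        )
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected (n, {model.n_features}) feature matrix, got {X.shape}"
        )
    scores = model.svc.decision_function(X)
    labels = (scores > 0).astype(int)
    return labels, scores


def save_model(model: TrainedModel, path: str | Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> TrainedModel:
    """Reload a persisted model; scores are bit-identical to pre-save."""
    with open(path, "rb") as fh:
        try:
            model = pickle.load(fh)
        except Exception as exc:  # corrupt or truncated file
            raise ValueError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(model, TrainedModel):
        raise ValueError(f"{path} does not contain a trained model")
    if model.n_features == N_FEATURES and model.fingerprint != layout_fingerprint():
        raise ValueError("saved model has a mismatched feature-layout fingerprint")
    return model
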