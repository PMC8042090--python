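"""The two linear classifiers used by both CV protocols.

* Soft-margin linear SVM — scikit-learn's ``SVC(kernel="linear")``; the
  fitted hyperplane is extracted so prediction goes through the same linear
  rule as RLDA (score >= 0 -> class 1).
* Regularized linear discriminant analysis (RLDA) — pooled within-class
  covariance S shrunk toward a scaled identity,

      S_gamma = (1 - gamma) S + gamma (trace(S) / d) I,

  discriminant w = S_gamma^{-1} (mu1 - mu0) with the intercept at the
  midpoint between the class means (equal priors; the designs here are
  balanced).  ``gamma="auto"`` estimates the shrinkage intensity from the
  training data with the Ledoit–Wolf formula, which keeps the rule usable
  when the feature count rivals the sample count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.svm import SVC


@dataclass
class ClassifierSpec:
    """Which linear classifier to fit and with what regularization."""

    kind: str = "svm"
    svm_cost: float = 1.0
    rlda_gamma: float | str = "auto"

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "rlda"):
            raise ValueError("kind must be 'svm' or 'rlda'")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be > 0")
        if isinstance(self.rlda_gamma, str):
            if self.rlda_gamma != "auto":
                raise ValueError("rlda_gamma must be in [0, 1] or 'auto'")
        elif not 0 <= self.rlda_gamma <= 1:
            raise ValueError("rlda_gamma must be in [0, 1] or 'auto'")


@dataclass
class TrainedModel:
    """A fitted linear rule: predict class 1 where X @ weights + intercept >= 0."""

    weights: np.ndarray
    intercept: float
    spec: ClassifierSpec
    feature_ids: list[str] | None = None
    gamma_used: float | None = None  # resolved RLDA shrinkage (None for SVM)


def _fit_rlda(X: np.ndarray, y: np.ndarray, gamma: float | str) -> tuple[np.ndarray, float, float]:
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    centered = np.vstack([X[y == 0] - mu0, X[y == 1] - mu1])
    n, d = X.shape
    S = centered.T @ centered / (n - 2)

    if gamma == "auto":
        gamma = float(ledoit_wolf_shrinkage(centered, assume_centered=True))
    gamma = float(gamma)
    target = (np.trace(S) / d) * np.eye(d)
    S_gamma = (1.0 - gamma) * S + gamma * target
    if gamma == 0.0 and np.linalg.matrix_rank(S) < d:
        raise ValueError(
            "pooled covariance is singular at gamma=0 (rank-deficient data); "
            "use gamma > 0 or 'auto'"
        )
    w = np.linalg.solve(S_gamma, mu1 - mu0)
    b = -float(w @ (mu0 + mu1) / 2.0)
    return w, b, gamma


def train(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: Sequence[int],
    feature_ids: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit the requested linear classifier on a training matrix.

    Requires at least two samples of each class and a finite matrix.  Returns
    the hyperplane (weights, intercept) on the training feature space.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != X.shape[0]:
        raise ValueError("label count must match row count")
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise ValueError("need >= 2 samples per class")
    if not np.isfinite(X).all():
        raise ValueError("training matrix has non-finite values")

    gamma_used = None
    if spec.kind == "svm":
        clf = SVC(kernel="linear", C=spec.svm_cost)
        clf.fit(X, y)
        w = clf.coef_.ravel().copy()
        b = float(clf.intercept_[0])
    else:
        w, b, gamma_used = _fit_rlda(X, y, spec.rlda_gamma)

    return TrainedModel(
        weights=w,
        intercept=b,
        spec=spec,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
        gamma_used=gamma_used,
    )


def decision_values(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(model.weights):
        raise ValueError(
            f"feature mismatch: model expects {len(model.weights)} features, got {X.shape[1]}"
        )
    return X @ model.weights + model.intercept


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Labels in {0, 1}; a point exactly on the boundary is assigned class 1."""
    return (decision_values(model, X) >= 0).astype(int)


def accuracy(pred: Sequence[int], truth: Sequence[int]) -> float:
    """Fraction of exact label matches."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    return float((pred == truth).mean())
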