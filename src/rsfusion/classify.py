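"""Soft-margin linear classification and decision/feature fusion.

The classifier is the standard hinge-loss soft-margin linear SVM (the
convex maximum-margin problem), trained on per-feature standardized inputs
with the standardization learned from the training subjects only. The
positive class is "patient": decision values d(x) = w.x - gamma >= 0 map to
the patient label. Decision-level fusion is a majority vote over three
single-family classifiers; feature-level fusion concatenates feature
families before selection and training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .selection import FeatureMatrix
from .synthetic import CONTROL, PATIENT

__all__ = [
    "LinearModel",
    "Prediction",
    "train_linear",
    "predict",
    "majority_vote",
    "feature_fusion",
]

DEFAULT_C = 10.0


def _fit_svc(values: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Fit a linear soft-margin SVM; returns (w, intercept)."""
    clf = SVC(kernel="linear", C=C)
    clf.fit(values, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


@dataclass(frozen=True)
class LinearModel:
    """Trained linear separator with its training standardization.

    Decision value d(x) = w . standardize(x) - offset; d >= 0 -> patient.
    """

    weights: np.ndarray
    offset: float
    C: float
    feature_ids: tuple
    train_mean: np.ndarray
    train_sd: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.feature_ids),):
            raise ValueError("weights length must equal feature_ids length")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "train_mean", np.asarray(self.train_mean, float))
        object.__setattr__(self, "train_sd", np.asarray(self.train_sd, float))

    def decision_values(self, values: np.ndarray) -> np.ndarray:
        z = (values - self.train_mean) / self.train_sd
        return z @ self.weights - self.offset

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "offset": self.offset,
                "C": self.C,
                "feature_ids": [list(f) if isinstance(f, tuple) else f
                                for f in self.feature_ids],
                "train_mean": self.train_mean.tolist(),
                "train_sd": self.train_sd.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        return cls(
            np.asarray(d["weights"]),
            float(d["offset"]),
            float(d["C"]),
            tuple(tuple(f) if isinstance(f, list) else f for f in d["feature_ids"]),
            np.asarray(d["train_mean"]),
            np.asarray(d["train_sd"]),
        )


@dataclass(frozen=True)
class Prediction:
    label: str
    decision_value: float


def train_linear(X: FeatureMatrix, C: float = DEFAULT_C) -> LinearModel:
    """Train the hinge-loss soft-margin linear separator with penalty C.

    Features are standardized with training-set mean/sd (zero-variance
    features get sd 1); the problem is convex, so retraining on identical
    input gives identical weights.
    """
    X.require_both_classes(minimum=1)
    if C <= 0:
        raise ValueError("C must be positive")
    mean = X.values.mean(axis=0)
    sd = X.values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (X.values - mean) / sd
    w, intercept = _fit_svc(z, X.y, C)
    # sklearn's decision function is w.x + b; ours is w.x - gamma.
    return LinearModel(w, -intercept, C, X.provenance, mean, sd)


def predict(model: LinearModel, X: FeatureMatrix) -> list[Prediction]:
    """Apply a trained model; d(x) >= 0 maps to the patient label."""
    if X.provenance != model.feature_ids:
        raise ValueError("feature columns do not match the model's features")
    d = model.decision_values(X.values)
    return [Prediction(PATIENT if di >= 0 else CONTROL, float(di)) for di in d]


def majority_vote(votes) -> list[str]:
    """Fuse three per-subject label votes into one label (2-of-3 rule)."""
    out = []
    for subject_votes in votes:
        subject_votes = list(subject_votes)
        if len(subject_votes) != 3:
            raise ValueError("majority vote requires exactly 3 votes per subject")
        n_pat = sum(v == PATIENT for v in subject_votes)
        out.append(PATIENT if n_pat >= 2 else CONTROL)
    return out


def feature_fusion(X_list: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature families (same subjects, same order).

    Downstream selection then operates on the fused matrix, so fusion happens
    before — not after — feature selection.
    """
    if not X_list:
        raise ValueError("need at least one feature matrix")
    first = X_list[0]
    for X in X_list[1:]:
        if not np.array_equal(X.labels, first.labels):
            raise ValueError("feature matrices must share subjects in the same order")
    provenance = tuple(p for X in X_list for p in X.provenance)
    if len(set(provenance)) < len(provenance):
        warnings.warn("fused matrix contains duplicated feature provenance",
                      stacklevel=2)
    values = np.hstack([X.values for X in X_list])
    return FeatureMatrix(values, first.labels, provenance)
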