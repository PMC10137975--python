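"""Gaussian-kernel SVM over texture feature vectors.

A binary normal (0) / abnormal (1) classifier.  Features are standardized
per column with the training-set mean and standard deviation before kernel
evaluation — the texture statistics live on wildly different scales, and an
RBF kernel on raw features would be dominated by the largest one.  The
quadratic program is solved by scikit-learn's SVC; this module owns the
data contract, scaling, and evaluation.

The confusion-matrix layout puts the abnormal class first on both axes:
rows are the true class (abnormal, normal), columns the predicted class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .texture import FEATURE_NAMES, FeatureVector

__all__ = [
    "NORMAL", "ABNORMAL",
    "LabeledDataset",
    "TrainedClassifier",
    "ConfusionMatrix",
    "train_svm",
    "predict",
    "evaluate",
    "accuracy",
]

NORMAL, ABNORMAL = 0, 1


def _as_feature_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray) and features.ndim == 2:
        X = features.astype(np.float64)
    else:
        rows = [f.as_array() if isinstance(f, FeatureVector) else
                np.asarray(f, dtype=np.float64) for f in features]
        X = np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X


@dataclass
class LabeledDataset:
    """Feature vectors with binary labels (0 = normal, 1 = abnormal)."""

    features: np.ndarray
    labels: np.ndarray
    ids: Sequence = field(default_factory=tuple)

    def __post_init__(self):
        self.features = _as_feature_matrix(self.features)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.features.shape[0]} feature rows but "
                f"{self.labels.shape[0]} labels")
        if not np.all(np.isin(self.labels, (NORMAL, ABNORMAL))):
            raise ValueError("labels must be 0 (normal) or 1 (abnormal)")

    def __len__(self) -> int:
        return int(self.labels.shape[0])


@dataclass
class TrainedClassifier:
    """Fitted standardize-then-RBF-SVM pipeline with its hyperparameters."""

    pipeline: Pipeline
    C: float
    gamma: float | str
    n_features: int

    @property
    def scaling_mean(self) -> np.ndarray:
        return self.pipeline.named_steps["scale"].mean_

    @property
    def scaling_sd(self) -> np.ndarray:
        return self.pipeline.named_steps["scale"].scale_


@dataclass
class ConfusionMatrix:
    """2x2 counts; rows = true (abnormal, normal), cols = predicted."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 2x2 non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def train_svm(data: LabeledDataset, C: float = 1.0,
              gamma: float | str = "scale", seed: int = 0
              ) -> TrainedClassifier:
    """Fit a soft-margin Gaussian-kernel SVM on standardized features.

    ``gamma='scale'`` (default) is 1 / (n_features * feature variance).
    Training requires at least two samples of each class; refitting with the
    same data and seed is deterministic.
    """
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    counts = np.bincount(data.labels, minlength=2)
    if counts[NORMAL] < 2 or counts[ABNORMAL] < 2:
        raise ValueError(
            f"need >= 2 samples per class, got normal={counts[NORMAL]}, "
            f"abnormal={counts[ABNORMAL]}")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)),
    ])
    pipe.fit(data.features, data.labels)
    return TrainedClassifier(pipeline=pipe, C=C, gamma=gamma,
                             n_features=data.features.shape[1])


def predict(clf: TrainedClassifier, features) -> np.ndarray:
    """Predict 0/1 labels; applies the stored scaling before the kernel."""
    X = _as_feature_matrix(features)
    if X.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    if X.shape[1] != clf.n_features:
        raise ValueError(f"expected {clf.n_features} features per sample, "
                         f"got {X.shape[1]}")
    return clf.pipeline.predict(X).astype(np.int64)


def evaluate(clf: TrainedClassifier, test: LabeledDataset) -> ConfusionMatrix:
    """Confusion matrix of the classifier on a labeled test set."""
    if len(test) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    pred = predict(clf, test.features)
    counts = np.zeros((2, 2), dtype=np.int64)
    # row/col 0 = abnormal, 1 = normal
    for true, p in zip(test.labels, pred):
        counts[1 - true, 1 - p] += 1
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples, trace / total."""
    if cm.total == 0:
        raise ValueError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)
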