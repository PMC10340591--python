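"""Random-forest origin classifier.

Thin scikit-learn wrapper fixing the study's vocabulary: ``n_trees`` for
the ensemble size and ``mtry`` for the number of candidate features
examined at each split (the R randomForest meaning of mtry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = ["RfConfig", "OriginRandomForestClassifier", "train_rf", "predict", "accuracy"]


@dataclass(frozen=True)
class RfConfig:
    """Forest hyperparameters; defaults are the study's selected operating
    point (2000 trees, 50 candidate features per split)."""

    n_trees: int = 2000
    mtry: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")


class OriginRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest over fused texture+shape features.

    No feature scaling is applied (trees are invariant to monotone
    per-feature rescaling).  Majority-vote ties between trees are resolved
    by the underlying forest's soft-voting rule: class probabilities are
    averaged over trees and the argmax taken, with exact ties going to the
    class that sorts first.
    """

    def __init__(self, n_trees: int = 2000, mtry: int = 50, seed: int | None = None, n_jobs: int = 1):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed
        self.n_jobs = n_jobs

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        if not 1 <= self.mtry <= X.shape[1]:
            raise ValueError(f"mtry={self.mtry} must lie in [1, {X.shape[1]}]")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain at least 2 classes")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.mtry,
            random_state=self.seed,
            n_jobs=self.n_jobs,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature-length mismatch: expected {self.n_features_in_} columns, got shape {X.shape}"
            )
        if X.shape[0] == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self.forest_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X))


def train_rf(train_X, train_y, cfg: RfConfig = RfConfig()) -> OriginRandomForestClassifier:
    """Fit a seeded, repeatable forest on a labelled training set."""
    return OriginRandomForestClassifier(n_trees=cfg.n_trees, mtry=cfg.mtry, seed=cfg.seed).fit(
        train_X, train_y
    )


def predict(model: OriginRandomForestClassifier, X) -> np.ndarray:
    """Predicted labels for a feature matrix."""
    return model.predict(X)


def accuracy(predicted, actual) -> float:
    """Percent of correct predictions: 100 · (#{PL_i = testY_i}) / m."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual label vectors must have equal length")
    if predicted.size == 0:
        raise ValueError("cannot score an empty test set")
    return float(100.0 * np.mean(predicted == actual))
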