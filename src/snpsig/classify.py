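"""Deterministic classifiers over encoded genotype codes.

The signature search only needs a classifier that is deterministic and free of
tuned hyperparameters, so the default is a nearest-centroid rule on the
Euclidean distance between a sample's code vector (restricted to the active
SNP subset) and each class's training mean vector. A k-nearest-neighbour vote
is available as an alternative. Tie handling is fixed so that every prediction
is reproducible:

* exact centroid-distance tie -> the majority class of the training set,
  a majority tie -> the first class (cases under the 1/2 label convention);
* k-NN neighbour-distance ties -> broken by training-sample order; with two
  classes and odd ``k`` the vote itself cannot tie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["ClassifierSpec", "CodeClassifier"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of the LOOCV/hold-out classifier."""

    method: str = "nearest_centroid"
    k: int = 5

    def __post_init__(self) -> None:
        if self.method not in ("nearest_centroid", "knn"):
            raise ValueError(f"unknown classifier method {self.method!r}")
        if self.method == "knn" and (self.k < 1 or self.k % 2 == 0):
            raise ValueError("k must be a positive odd integer for knn")

    def make(self) -> "CodeClassifier":
        return CodeClassifier(method=self.method, k=self.k)


class CodeClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-centroid (default) or odd-k k-NN classifier with fixed tie rules."""

    def __init__(self, method: str = "nearest_centroid", k: int = 5):
        self.method = method
        self.k = k

    def fit(self, X, y):
        ClassifierSpec(self.method, self.k)  # validate parameters
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"training set must contain both classes, got {self.classes_}"
            )
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        self.centroids_ = np.stack(
            [X[y == c].mean(axis=0) for c in self.classes_]
        )
        counts = np.array([(y == c).sum() for c in self.classes_])
        # majority class of the training set; count tie -> first class
        self.majority_ = self.classes_[int(np.argmax(counts))]
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of features than at fit")
        if self.method == "nearest_centroid":
            return self._predict_centroid(X)
        return self._predict_knn(X)

    def _predict_centroid(self, X):
        d = np.stack(
            [((X - c) ** 2).sum(axis=1) for c in self.centroids_], axis=1
        )
        pred = self.classes_[np.argmin(d, axis=1)]
        tie = d[:, 0] == d[:, 1]
        pred[tie] = self.majority_
        return pred

    def _predict_knn(self, X):
        k = min(self.k, len(self.X_))
        d = ((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        # stable sort: equal distances resolve by training-sample order
        nearest = np.argsort(d, axis=1, kind="stable")[:, :k]
        votes = self.y_[nearest]
        pred = np.empty(len(X), dtype=self.y_.dtype)
        for i in range(len(X)):
            c0 = (votes[i] == self.classes_[0]).sum()
            pred[i] = self.classes_[0] if c0 * 2 >= k else self.classes_[1]
        return pred
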