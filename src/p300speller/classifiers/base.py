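"""Common contract for all speller classifiers.

Every classifier is fitted on a balanced training set of Z-scored,
averaged responses with labels +1 (target) / -1 (nontarget), and then
maps a feature vector to a signed real score — the "distance" to the
class boundary, positive meaning target.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np

from ..preprocessing import TrainingSet

__all__ = ["BoundaryClassifier", "score"]


class BoundaryClassifier(ABC):
    """Fit on (X, y) with y in {-1, +1}; score via signed distance."""

    n_features_in_: int

    @abstractmethod
    def fit(self, X: np.ndarray, y: np.ndarray) -> "BoundaryClassifier":
        ...

    @abstractmethod
    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed scores, one per row of X (or a scalar for a 1-D input)."""
        ...

    def fit_training_set(self, ts: TrainingSet) -> "BoundaryClassifier":
        return self.fit(ts.features, ts.labels)

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_function(X)
        return np.where(np.asarray(s) >= 0, 1, -1)

    def _validate_fit_args(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D [n_examples, n_features]")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("labels must be +/-1")
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes present")
        self.n_features_in_ = X.shape[1]
        return X, y

    def _validate_score_input(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X


def score(model: BoundaryClassifier, f: np.ndarray) -> float:
    """Signed distance of a single feature vector to the class boundary."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 1:
        raise ValueError("score expects a single feature vector")
    return float(model.decision_function(f[None, :])[0])
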