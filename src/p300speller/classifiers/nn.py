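"""Single-hidden-layer feed-forward network trained as a least-squares fit.

The network is

    y(f) = sum_{i=1..M} w2_i * F( sum_j w1_{ji} f_j + b1_i ) + b,
    F(t) = 1 / (1 + exp(t)),

with NM + 2M + 1 free parameters, trained toward the +/-1 labels by a
second-order least-squares optimizer (trust-region Gauss-Newton with an
analytic Jacobian).  The hidden-layer size M is chosen by a 5-fold
cross-validated line search over M = 1..20 (ties toward the smaller M);
the winning network is retrained on the whole training set.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from sklearn.model_selection import StratifiedKFold

from .base import BoundaryClassifier

__all__ = ["SigmoidNet", "n_parameters"]


def n_parameters(n_features: int, n_hidden: int) -> int:
    """Free parameters of the network: N*M input weights, M output
    weights, M hidden thresholds and one output threshold."""
    return n_features * n_hidden + 2 * n_hidden + 1


def _sigmoid(t):
    return 1.0 / (1.0 + np.exp(np.clip(t, -500, 500)))


def _unpack(theta, N, M):
    W1 = theta[: N * M].reshape(N, M)
    b1 = theta[N * M : N * M + M]
    w2 = theta[N * M + M : N * M + 2 * M]
    b = theta[-1]
    return W1, b1, w2, b


def _forward(theta, X, N, M):
    W1, b1, w2, b = _unpack(theta, N, M)
    S = _sigmoid(X @ W1 + b1)
    return S @ w2 + b, S, w2


def _fit_single(X, y, M, rng, max_nfev):
    n, N = X.shape

    def residuals(theta):
        out, _, _ = _forward(theta, X, N, M)
        return out - y

    def jacobian(theta):
        out, S, w2 = _forward(theta, X, N, M)
        dS = -S * (1.0 - S)  # F'(t) for the decreasing sigmoid
        J = np.empty((n, n_parameters(N, M)))
        core = dS * w2  # [n, M]
        # d/dW1[j,i] = x_j * w2_i * F'_i  -> block ordered (j, i)
        J[:, : N * M] = (X[:, :, None] * core[:, None, :]).reshape(n, N * M)
        J[:, N * M : N * M + M] = core
        J[:, N * M + M : N * M + 2 * M] = S
        J[:, -1] = 1.0
        return J

    theta0 = rng.normal(scale=1.0 / np.sqrt(N + 1), size=n_parameters(N, M))
    res = least_squares(
        residuals, theta0, jac=jacobian, method="trf", tr_solver="lsmr",
        max_nfev=max_nfev,
    )
    return res.x, res.cost


class SigmoidNet(BoundaryClassifier):
    """MLP with one sigmoidal hidden layer and a linear output unit.

    ``max_hidden`` bounds the cross-validated line search over the
    hidden-layer size.  A diverged fit (non-finite cost) is retried with
    a fresh random initialization up to ``max_retries`` times.
    """

    def __init__(self, max_hidden: int = 20, cv: int = 5, seed: int = 0,
                 max_nfev: int = 60, cv_max_nfev: int | None = 40,
                 max_retries: int = 3):
        if not 1 <= max_hidden <= 20:
            raise ValueError("hidden-layer search space is 1..20")
        self.max_hidden = max_hidden
        self.cv = cv
        self.seed = seed
        self.max_nfev = max_nfev
        self.cv_max_nfev = cv_max_nfev if cv_max_nfev is not None else max_nfev
        self.max_retries = max_retries

    @property
    def candidate_hidden_sizes_(self):
        return list(range(1, self.max_hidden + 1))

    def _robust_fit(self, X, y, M, rng, max_nfev):
        for _ in range(self.max_retries + 1):
            theta, cost = _fit_single(X, y, M, rng, max_nfev)
            if np.isfinite(cost):
                return theta
        raise RuntimeError(f"optimizer diverged for M={M} after retries")

    def fit(self, X, y):
        X, y = self._validate_fit_args(X, y)
        n, N = X.shape
        rng = np.random.default_rng(self.seed)
        best_M, best_acc = None, -1.0
        if self.max_hidden == 1:
            best_M = 1
        else:
            cv = StratifiedKFold(n_splits=self.cv, shuffle=True,
                                 random_state=self.seed)
            folds = list(cv.split(X, y))
            for M in self.candidate_hidden_sizes_:  # ascending: ties -> smaller M
                correct = total = 0
                for tr, te in folds:
                    theta = self._robust_fit(X[tr], y[tr], M, rng, self.cv_max_nfev)
                    out, _, _ = _forward(theta, X[te], N, M)
                    correct += int(np.sum(np.sign(out) == y[te]))
                    total += len(te)
                acc = correct / total
                if acc > best_acc:
                    best_acc, best_M = acc, M
            self.cv_accuracy_ = best_acc
        self.n_hidden_ = best_M
        self._theta = self._robust_fit(X, y, best_M, rng, self.max_nfev)
        W1, b1, w2, b = _unpack(self._theta, N, best_M)
        self.input_weights_ = W1
        self.hidden_thresholds_ = b1
        self.output_weights_ = w2
        self.output_threshold_ = float(b)
        return self

    def decision_function(self, X):
        X = self._validate_score_input(X)
        out, _, _ = _forward(self._theta, X, self.n_features_in_, self.n_hidden_)
        return out
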