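"""Linear feature-extraction classifier: one-dimensional projection
maximizing a negentropy-based estimate of mutual information.

The direction w (unit norm) maximizes

    I(Y, C) = sum_p  p(t_p) * ( J(Y | t_p) - log sigma(Y | t_p) ) - J(Y)

where Y = {w^T f_i} are the projections, Y | t_p the projections of
class p, sigma the standard deviation and J the negentropy approximated
with the robust two-term contrast

    J(u) ~= k1 * E[u exp(-u^2/2)]^2 + k2 * ( E[exp(-u^2/2)] - sqrt(1/2) )^2

evaluated on standardized u, with k1 = 36/(8 sqrt(3) - 9) and
k2 = 24/(16 sqrt(3) - 27).  Optimization is normalized-gradient ascent
on the unit sphere with backtracking line search and random restarts;
the gradient is a forward-difference through precomputed projections, so
one gradient costs one pass over the n x N data matrix.
"""

from __future__ import annotations

import numpy as np

from .base import BoundaryClassifier

__all__ = ["NegentropyProjection", "mutual_information_objective", "negentropy"]

_K1 = 36.0 / (8.0 * np.sqrt(3.0) - 9.0)
_K2 = 24.0 / (16.0 * np.sqrt(3.0) - 27.0)


def negentropy(y: np.ndarray) -> float:
    """Two-term robust negentropy approximation of a 1-D sample."""
    y = np.asarray(y, dtype=float)
    sd = y.std()
    if sd <= 0:
        return 0.0
    u = (y - y.mean()) / sd
    g = np.exp(-0.5 * u**2)
    return float(_K1 * np.mean(u * g) ** 2 + _K2 * (np.mean(g) - np.sqrt(0.5)) ** 2)


def _negentropy_cols(Y: np.ndarray) -> np.ndarray:
    """Column-wise two-term negentropy of an [n, m] projection matrix."""
    sd = Y.std(axis=0)
    sd = np.where(sd > 0, sd, np.inf)
    U = (Y - Y.mean(axis=0)) / sd
    G = np.exp(-0.5 * U**2)
    return _K1 * np.mean(U * G, axis=0) ** 2 + _K2 * (
        np.mean(G, axis=0) - np.sqrt(0.5)
    ) ** 2


def _objective_cols(Y: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mutual-information objective per column of an [n, m] projection matrix.

    The projections are first normalized to unit overall variance: the
    negentropy decomposition of the differential entropy,
    H(Y) = H_gauss(sigma(Y)) - J(Y), makes the mutual information
    I(Y, C) = sum_p p(t_p) (J(Y|t_p) - log sigma(Y|t_p)) - J(Y)
    exact only when sigma(Y) = 1 (otherwise a + log sigma(Y) term
    remains); without the normalization the criterion would reward
    low-variance directions regardless of the labels.
    """
    n = Y.shape[0]
    sd_all = Y.std(axis=0)
    Y = Y / np.where(sd_all > 0, sd_all, np.inf)
    total = np.zeros(Y.shape[1])
    for cls in (-1.0, 1.0):
        Yc = Y[y == cls]
        sd = Yc.std(axis=0)
        with np.errstate(divide="ignore"):
            total += (len(Yc) / n) * (
                _negentropy_cols(Yc) - np.where(sd > 0, np.log(sd), np.inf)
            )
    return total - _negentropy_cols(Y)


def mutual_information_objective(Y: np.ndarray, y: np.ndarray) -> float:
    """Negentropy-based mutual-information estimate between projections and labels."""
    Y = np.asarray(Y, dtype=float)
    val = _objective_cols(Y[:, None], np.asarray(y, dtype=float))[0]
    return float(val) if np.isfinite(val) else -np.inf


class NegentropyProjection(BoundaryClassifier):
    """Unit-norm discriminative projection by mutual-information ascent.

    ``n_restarts`` random unit directions are each refined by projected
    gradient ascent with backtracking; the best final direction wins.
    After fitting, the sign of w is flipped if needed so that target
    examples project positively.  ``low_information_`` is set when the
    best objective is below ``info_threshold`` (classes essentially
    indistinguishable along any direction found), and ``improved_`` is
    False when no restart improved on its random initialization.
    """

    def __init__(self, n_restarts: int = 20, max_iter: int = 200,
                 tol: float = 1e-9, step0: float = 0.5,
                 info_threshold: float = 1e-2, seed: int = 0):
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.step0 = step0
        self.info_threshold = info_threshold
        self.seed = seed

    def fit(self, X, y):
        X, y = self._validate_fit_args(X, y)
        n, N = X.shape
        rng = np.random.default_rng(self.seed)

        def objective_from_proj(Y):
            val = _objective_cols(Y[:, None], y)[0]
            return float(val) if np.isfinite(val) else -np.inf

        def gradient(w, Y, f0, h=1e-6):
            # forward difference; Y + h X[:, j] is the projection of w + h e_j
            return (_objective_cols(Y[:, None] + h * X, y) - f0) / h

        best_w, best_obj, improved = None, -np.inf, False
        for _ in range(self.n_restarts):
            w = rng.normal(size=N)
            w /= np.linalg.norm(w)
            Y = X @ w
            f0 = objective_from_proj(Y)
            init_obj = f0
            for _ in range(self.max_iter):
                g = gradient(w, Y, f0)
                g_t = g - (g @ w) * w  # tangent to the unit sphere
                gn = np.linalg.norm(g_t)
                if gn < 1e-12:
                    break
                step, accepted = self.step0, False
                while step > 1e-8:
                    w_new = w + step * g_t / gn
                    w_new /= np.linalg.norm(w_new)
                    Y_new = X @ w_new
                    f_new = objective_from_proj(Y_new)
                    if f_new > f0 + 1e-12:
                        w, Y, gain, f0 = w_new, Y_new, f_new - f0, f_new
                        accepted = True
                        break
                    step /= 2.0
                if not accepted or gain < self.tol:
                    break
            if f0 > init_obj + 1e-12:
                improved = True
            if f0 > best_obj:
                best_obj, best_w = f0, w
        # orient so that targets project positively
        if np.mean(X[y > 0] @ best_w) < np.mean(X[y < 0] @ best_w):
            best_w = -best_w
        self.weights_ = best_w
        self.bias_ = 0.0
        self.objective_ = best_obj
        self.low_information_ = best_obj < self.info_threshold
        self.improved_ = improved
        return self

    def decision_function(self, X):
        X = self._validate_score_input(X)
        return X @ self.weights_ + self.bias_
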