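"""Least-squares linear SVM and Gaussian-kernel SVM with grid search.

The linear classifier solves the least-squares SVM problem

    min_{w,b,e}  (1/2) w^T w + gamma * sum_i e_i^2
    s.t.         y_i (w^T f_i + b) = 1 - e_i

Because the labels are +/-1, the equality constraints make this a ridge
regression of y onto [X | 1] with penalty 1/(2 gamma) on w (none on b),
which is how it is solved here; the KKT dual system gives the identical
solution and serves as an independent oracle in the tests.  gamma is
chosen by a cross-validated line search over half-decade steps.

The nonlinear classifier is a soft-margin SVM with the Gaussian RBF
kernel K(f_i, f_j) = exp(-gamma ||f_i - f_j||^2), with (C, gamma)
selected by 5-fold cross-validation on the 8 x 8 geometric grid
C in 2^{-5}, 2^{-2}, ..., 2^{16} and gamma in 2^{-15}, 2^{-12}, ..., 2^6.
The per-point quadratic program is delegated to sklearn's SVC; the grid
search, tie-breaking and refit policy live here.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .base import BoundaryClassifier

__all__ = ["LinearLSSVM", "KernelSVM", "LSSVM_GAMMA_GRID", "RBF_C_GRID", "RBF_GAMMA_GRID"]

#: Half-decade line-search grid for the LS-SVM regularization weight.
LSSVM_GAMMA_GRID = tuple(10.0 ** e for e in np.arange(-3.0, 3.0 + 0.25, 0.5))

#: 8 x 8 geometric (C, gamma) grid with ratio 2^3 for the RBF SVM.
RBF_C_GRID = tuple(2.0 ** e for e in range(-5, 17, 3))
RBF_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 7, 3))


def _cv_accuracy(make_model, X, y, n_splits, seed):
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = total = 0
    for tr, te in cv.split(X, y):
        m = make_model().fit(X[tr], y[tr])
        correct += int(np.sum(m.predict(X[te]) == y[te]))
        total += len(te)
    return correct / total


class LinearLSSVM(BoundaryClassifier):
    """Linear least-squares SVM; gamma by 5-fold cross-validated line search.

    With ``gamma`` given, the model is fitted directly at that value.
    Ties in cross-validated accuracy break toward the smaller gamma
    (stronger regularization).
    """

    def __init__(self, gamma: float | None = None,
                 gamma_grid=LSSVM_GAMMA_GRID, cv: int = 5, seed: int = 0):
        self.gamma = gamma
        self.gamma_grid = tuple(gamma_grid)
        self.cv = cv
        self.seed = seed

    def fit(self, X, y):
        X, y = self._validate_fit_args(X, y)
        if self.gamma is not None:
            self.gamma_ = float(self.gamma)
        else:
            best_acc, best_gamma = -1.0, None
            for g in self.gamma_grid:  # ascending; strict > keeps the smallest
                acc = _cv_accuracy(
                    lambda g=g: LinearLSSVM(gamma=g), X, y, self.cv, self.seed
                )
                if acc > best_acc:
                    best_acc, best_gamma = acc, g
            self.gamma_ = float(best_gamma)
            self.cv_accuracy_ = best_acc
        self.weights_, self.bias_ = _lssvm_primal(X, y, self.gamma_)
        return self

    def decision_function(self, X):
        X = self._validate_score_input(X)
        return X @ self.weights_ + self.bias_


def _lssvm_primal(X, y, gamma):
    """Condensed primal solve: ridge of y on [X | 1], penalty 1/(2 gamma) on w."""
    n, N = X.shape
    Z = np.column_stack([X, np.ones(n)])
    A = Z.T @ Z
    A[:N, :N] += np.eye(N) / (2.0 * gamma)
    try:
        beta = np.linalg.solve(A, Z.T @ y)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular LS-SVM system") from err
    return beta[:N], float(beta[N])


class KernelSVM(BoundaryClassifier):
    """Gaussian-RBF soft-margin SVM with cross-validated (C, gamma).

    The grid is scanned with C ascending in the outer loop and gamma
    ascending in the inner loop; only a strictly better cross-validated
    accuracy replaces the incumbent, so ties resolve to the smallest C,
    then the smallest gamma.  The winning pair is refitted on all data.
    """

    def __init__(self, C_grid=RBF_C_GRID, gamma_grid=RBF_GAMMA_GRID,
                 cv: int = 5, seed: int = 0):
        self.C_grid = tuple(C_grid)
        self.gamma_grid = tuple(gamma_grid)
        self.cv = cv
        self.seed = seed

    @property
    def param_grid_(self):
        return [(C, g) for C in self.C_grid for g in self.gamma_grid]

    def fit(self, X, y):
        X, y = self._validate_fit_args(X, y)
        best = (-1.0, None, None)
        for C in self.C_grid:
            for g in self.gamma_grid:
                acc = _cv_accuracy(
                    lambda C=C, g=g: SVC(C=C, gamma=g, kernel="rbf"),
                    X, y, self.cv, self.seed,
                )
                if acc > best[0]:
                    best = (acc, C, g)
        self.cv_accuracy_, self.C_, self.gamma_ = best
        self._svc = SVC(C=self.C_, gamma=self.gamma_, kernel="rbf").fit(X, y)
        self.support_vectors_ = self._svc.support_vectors_
        self.dual_weights_ = self._svc.dual_coef_.ravel()  # alpha_i * y_i
        self.bias_ = float(self._svc.intercept_[0])
        return self

    def decision_function(self, X):
        X = self._validate_score_input(X)
        return self._svc.decision_function(X)
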