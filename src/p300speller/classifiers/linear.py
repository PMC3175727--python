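"""Fisher's LDA and stepwise LDA (regression-based feature selection).

Fisher's discriminant uses the classical two-class solution
``w = (S_-1 + S_+1)^-1 (mu_+1 - mu_-1)`` where the S are the class
sample covariances.  Stepwise LDA wraps the same linear read-out in a
forward/backward feature-selection loop driven by regression
significance: a candidate enters while its partial-F p-value is below
0.1, a retained term leaves when its p-value rises above 0.15, and the
model never grows beyond 60 features.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .base import BoundaryClassifier

__all__ = ["FisherLDA", "StepwiseLDA", "EmptyModelError"]


class EmptyModelError(RuntimeError):
    """No feature ever met the entry criterion."""


class FisherLDA(BoundaryClassifier):
    """Two-class Fisher discriminant with a trace-scaled ridge fallback.

    If the summed class covariance is near-singular, ``ridge`` times the
    average eigenvalue (trace/N) is added to the diagonal before solving.
    The bias centres the balanced training set: the mean of the two class
    mean scores is zero.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X, y = self._validate_fit_args(X, y)
        Xp, Xn = X[y > 0], X[y < 0]
        mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
        S = np.cov(Xp, rowvar=False, ddof=1) + np.cov(Xn, rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        dmu = mu_p - mu_n
        try:
            c, low = _cholesky(S)
            w = _cho_solve(c, low, dmu)
        except np.linalg.LinAlgError:
            S_reg = S + self.ridge * (np.trace(S) / S.shape[0]) * np.eye(S.shape[0])
            try:
                c, low = _cholesky(S_reg)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "class covariance singular even after regularization"
                ) from err
            w = _cho_solve(c, low, dmu)
        self.weights_ = w
        self.bias_ = -float(w @ (mu_p + mu_n)) / 2.0
        return self

    def decision_function(self, X):
        X = self._validate_score_input(X)
        return X @ self.weights_ + self.bias_


def _cholesky(S):
    from scipy.linalg import cho_factor

    return cho_factor(S, lower=True)


def _cho_solve(c, low, b):
    from scipy.linalg import cho_solve

    return cho_solve((c, low), b)


class StepwiseLDA(BoundaryClassifier):
    """Forward/backward stepwise linear discriminant on +/-1 labels.

    Forward step: among features not in the model, enter the one with the
    smallest partial-F p-value if it is below ``enter_p``.  Backward
    step: refit the ordinary least-squares model on the retained features
    and drop the term with the largest t-test p-value while it exceeds
    ``exit_p``.  Iterate to convergence or ``max_features``.  Ties break
    toward the lower feature index; exactly collinear candidates can
    never enter (their residual norm is ~0), so of a duplicated feature
    pair only the first is retained.
    """

    def __init__(self, enter_p: float = 0.1, exit_p: float = 0.15,
                 max_features: int = 60, max_sweeps: int = 200):
        self.enter_p = enter_p
        self.exit_p = exit_p
        self.max_features = max_features
        self.max_sweeps = max_sweeps

    def fit(self, X, y):
        X, y = self._validate_fit_args(X, y)
        n, N = X.shape
        selected: list[int] = []
        # Q holds an orthonormal basis of [intercept | selected columns].
        Q = np.ones((n, 1)) / np.sqrt(n)

        def orthonormalize(col):
            r = col - Q @ (Q.T @ col)
            nrm = np.linalg.norm(r)
            return r / nrm if nrm > 1e-10 * max(1.0, np.linalg.norm(col)) else None

        for _ in range(self.max_sweeps):
            changed = False
            # ---- forward entry ----
            if len(selected) < self.max_features:
                resid_y = y - Q @ (Q.T @ y)
                rss = float(resid_y @ resid_y)
                XR = X - Q @ (Q.T @ X)
                ssx = np.einsum("ij,ij->j", XR, XR)
                colnorm = np.einsum("ij,ij->j", X, X)
                ok = ssx > 1e-10 * np.maximum(colnorm, 1.0)
                ok[selected] = False
                df = n - len(selected) - 2  # intercept + selected + candidate
                if df > 0 and ok.any():
                    gain = np.zeros(N)
                    gain[ok] = (XR[:, ok].T @ resid_y) ** 2 / ssx[ok]
                    rss_new = np.maximum(rss - gain, 1e-300)
                    F = gain / (rss_new / df)
                    p = np.full(N, np.inf)
                    p[ok] = stats.f.sf(F[ok], 1, df)
                    best = int(np.argmin(p))  # argmin ties -> lowest index
                    if p[best] < self.enter_p:
                        q = orthonormalize(X[:, best])
                        if q is not None:
                            selected.append(best)
                            Q = np.column_stack([Q, q])
                            changed = True
            # ---- backward removal ----
            while selected:
                pvals = _ols_term_pvalues(X[:, selected], y)
                worst = int(np.argmax(pvals))
                if pvals[worst] > self.exit_p:
                    del selected[worst]
                    Q = _rebuild_basis(X, selected)
                    changed = True
                else:
                    break
            if not changed:
                break
        if not selected:
            raise EmptyModelError("no feature met the entry criterion")
        self.selected_features_ = list(selected)
        Z = np.column_stack([np.ones(n), X[:, selected]])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        self.bias_ = float(beta[0])
        self.weights_ = beta[1:]
        return self

    def decision_function(self, X):
        X = self._validate_score_input(X)
        return X[:, self.selected_features_] @ self.weights_ + self.bias_


def _rebuild_basis(X, selected):
    n = X.shape[0]
    Z = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
    Q, _ = np.linalg.qr(Z)
    return Q


def _ols_term_pvalues(Xsel, y):
    """Two-sided t-test p-values of the non-intercept OLS coefficients."""
    n = Xsel.shape[0]
    Z = np.column_stack([np.ones(n), Xsel])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    df = n - Z.shape[1]
    if df <= 0:
        return np.zeros(Xsel.shape[1])
    s2 = float(resid @ resid) / df
    XtX_inv = np.linalg.pinv(Z.T @ Z)
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 1e-300))
    t = beta / se
    return stats.t.sf(np.abs(t[1:]), df) * 2
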