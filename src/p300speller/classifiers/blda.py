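"""Bayesian linear discriminant analysis (evidence-maximized ridge).

The model regresses the +/-1 labels on the features with Gaussian noise
(variance sigma^2) and an isotropic zero-mean Gaussian prior on the
weights (precision alpha).  The posterior is Gaussian with

    mu    = (F^T F + sigma^2 alpha I)^-1 F^T t
    Sigma = sigma^2 (F^T F + sigma^2 alpha I)^-1

and the separating hyperplane is ``mu^T f``.  At fixed hyperparameters
this is exactly ridge regression with penalty lambda = sigma^2 alpha.
The hyperparameters are tuned automatically by fixed-point evidence
maximization using the effective number of well-determined parameters

    nu      = sum_i  lam_i / (lam_i + sigma^2 alpha)
    alpha  <- nu / ||mu||^2
    sigma^2 <- ||t - F mu||^2 / (n - nu)

over the eigenvalues lam_i of F^T F, iterated until the relative change
of both hyperparameters falls below ``tol``.
"""

from __future__ import annotations



import numpy as np

from .base import BoundaryClassifier

__all__ = ["BayesianLDA"]


class BayesianLDA(BoundaryClassifier):
    """Probabilistic linear discriminant with automatic regularization.

    Parameters
    ----------
    alpha, noise_variance
        Initial (or, with ``optimize=False``, fixed) prior precision and
        noise variance.
    optimize
        Run the evidence fixed-point iteration; disable to obtain the
        closed-form posterior at the given hyperparameters.
    tol, max_iter
        Convergence tolerance on the relative hyperparameter change and
        the iteration cap.  Non-convergence raises, with the iteration
        trace attached to the exception.
    """

    def __init__(self, alpha: float = 1.0, noise_variance: float = 1.0,
                 optimize: bool = True, tol: float = 1e-6, max_iter: int = 500,
                 alpha_max: float = 1e10):
        self.alpha = alpha
        self.noise_variance = noise_variance
        self.optimize = optimize
        self.tol = tol
        self.max_iter = max_iter
        # when the labels carry no information the fixed point drives
        # alpha to infinity geometrically (all weights shrink to zero);
        # reaching this bound is the converged no-signal limit
        self.alpha_max = alpha_max

    def fit(self, X, y):
        # a regression network: +/-1 class labels are the speller use case,
        # but any real-valued targets are admissible
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D and match y in length")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite training data")
        self.n_features_in_ = X.shape[1]
        n, N = X.shape
        gram = X.T @ X
        lam, V = np.linalg.eigh(gram)
        lam = np.maximum(lam, 0.0)
        Vt_Xt_y = V.T @ (X.T @ y)
        alpha, s2 = float(self.alpha), float(self.noise_variance)

        def posterior_mean(alpha, s2):
            return V @ (Vt_Xt_y / (lam + s2 * alpha))

        trace: list[tuple[float, float]] = [(alpha, s2)]
        if self.optimize:
            converged = False
            for _ in range(self.max_iter):
                mu = posterior_mean(alpha, s2)
                nu = float(np.sum(lam / (lam + s2 * alpha)))
                resid = y - X @ mu
                alpha_new = nu / max(float(mu @ mu), 1e-300)
                s2_new = float(resid @ resid) / max(n - nu, 1e-12)
                trace.append((alpha_new, s2_new))
                rel = max(abs(alpha_new - alpha) / max(alpha, 1e-300),
                          abs(s2_new - s2) / max(s2, 1e-300))
                alpha, s2 = alpha_new, s2_new
                if alpha >= self.alpha_max:
                    alpha = self.alpha_max
                    converged = True
                    break
                if rel < self.tol:
                    converged = True
                    break
            if not converged:
                err = RuntimeError(
                    f"evidence iteration did not converge in {self.max_iter} steps"
                )
                err.iteration_trace = trace
                raise err
        self.alpha_ = alpha
        self.noise_variance_ = s2
        self.iteration_trace_ = trace
        self.posterior_mean_ = posterior_mean(alpha, s2)
        self.effective_dof_ = float(np.sum(lam / (lam + s2 * alpha)))
        self._eig = (lam, V)
        return self

    @property
    def posterior_covariance_(self) -> np.ndarray:
        lam, V = self._eig
        return self.noise_variance_ * (
            V @ (V / (lam + self.noise_variance_ * self.alpha_)).T
        )

    def decision_function(self, X):
        X = self._validate_score_input(X)
        return X @ self.posterior_mean_
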