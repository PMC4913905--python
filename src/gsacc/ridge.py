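"""Ridge-regression BLUP (RRBLUP / GBLUP) marker-effect model.

The predictor is beta_hat = (X'X + lambda I)^-1 X'y, computed through
its dual (Woodbury) form beta_hat = X' V^-1 y with V = XX' + lambda I,
so the cost is governed by the number of training individuals rather
than the number of markers.  The regularization parameter
lambda = sigma_eps^2 / sigma_beta^2 is either supplied, derived from
the trait heritability, or estimated by REML for the one-random-effect
model y = X beta + eps, beta ~ N(0, sigma_beta^2 I).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["RRBLUP", "estimate_lambda_reml", "estimate_lambda_h2", "fit", "predict"]

# lambda cap multiplier used when sigma_beta^2 collapses to the boundary
_LAMBDA_CAP = 1e8


def estimate_lambda_h2(X: np.ndarray, h2: float) -> float:
    """Heritability route: lambda = (1-h2)/(n h2) * sum_ij X_ij^2.

    Assumes the genetic variance is spread uniformly over all (filtered)
    markers; X is the centered training marker matrix.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie strictly between 0 and 1")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    return (1.0 - h2) / (n * h2) * float(np.sum(X * X))


def estimate_lambda_reml(X: np.ndarray, y: np.ndarray,
                         lam_bounds: tuple[float, float] = (1e-8, 1e8)):
    """REML estimates (sigma_eps^2, sigma_beta^2, lambda) of the ridge model.

    Uses the spectral decomposition of K = XX' to reduce REML for
    y = mu + X beta + eps (beta ~ N(0, sigma_beta^2 I)) to a bounded 1-D
    optimization over lambda = sigma_eps^2/sigma_beta^2; the fixed
    intercept is absorbed by generalized least squares.  When the marker
    variance collapses to zero (null trait) lambda is set to a large cap
    and flagged with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 2 or y.size != n:
        raise ValueError("need at least 2 training individuals and matching y")
    if not np.any(X):
        raise ValueError("X has no nonzero column")

    K = X @ X.T
    s, U = linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    ty = U.T @ y
    tone = U.T @ np.ones(n)

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = s + lam
        # GLS fit of the intercept
        w11 = np.sum(tone**2 / d)
        w1y = np.sum(tone * ty / d)
        mu = w1y / w11
        rss = np.sum((ty - mu * tone) ** 2 / d)
        sb2 = rss / (n - 1)
        return (n - 1) * np.log(sb2) + np.sum(np.log(d)) + np.log(w11)

    lo, hi = np.log(lam_bounds[0]), np.log(lam_bounds[1])
    res = optimize.minimize_scalar(neg2_reml, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    d = s + lam
    w11 = np.sum(tone**2 / d)
    mu = np.sum(tone * ty / d) / w11
    sigma_beta2 = float(np.sum((ty - mu * tone) ** 2 / d) / (n - 1))
    sigma_eps2 = lam * sigma_beta2
    if sigma_beta2 <= 0 or lam >= lam_bounds[1] * 0.99:
        cap = _LAMBDA_CAP * np.trace(K) / n
        warnings.warn("sigma_beta^2 numerically zero; lambda set to cap",
                      RuntimeWarning)
        lam = float(cap)
    return sigma_eps2, sigma_beta2, lam


class RRBLUP(RegressorMixin, BaseEstimator):
    """Ridge-regression BLUP of marker effects.

    Parameters
    ----------
    alpha : float, optional
        Fixed regularization parameter lambda.  Ignored unless
        ``method="fixed"``.
    method : {"reml", "h2", "fixed"}
        How lambda is obtained: REML variance components, the
        heritability formula (requires ``h2``), or ``alpha`` as given.
    h2 : float, optional
        Trait heritability for ``method="h2"``.

    Attributes
    ----------
    lambda_ : float
        Regularization parameter used in the fit.
    beta_ : ndarray of shape (p,)
        Estimated marker effects X' V^-1 y.
    v_inv_y_ : ndarray of shape (n,)
        Work vector V^-1 y.
    sigma_beta2_, sigma_eps2_ : float
        REML variance components (only for ``method="reml"``).
    """

    def __init__(self, alpha: float | None = None, method: str = "reml",
                 h2: float | None = None):
        self.alpha = alpha
        self.method = method
        self.h2 = h2

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per phenotype")
        if self.method == "reml":
            self.sigma_eps2_, self.sigma_beta2_, lam = estimate_lambda_reml(X, y)
        elif self.method == "h2":
            if self.h2 is None:
                raise ValueError('method="h2" requires the h2 parameter')
            lam = estimate_lambda_h2(X, self.h2)
        elif self.method == "fixed":
            if self.alpha is None:
                raise ValueError('method="fixed" requires alpha')
            lam = float(self.alpha)
        else:
            raise ValueError(f"unknown lambda method {self.method!r}")
        if lam < 0:
            raise ValueError("lambda must be non-negative")

        n = X.shape[0]
        V = X @ X.T + lam * np.eye(n)
        try:
            cho = linalg.cho_factor(V)
        except linalg.LinAlgError:
            raise linalg.LinAlgError(
                "V = XX' + lambda I is singular (lambda = %g with "
                "rank-deficient XX'); use a positive lambda" % lam) from None
        self.v_inv_y_ = linalg.cho_solve(cho, y)
        self._v_cho = cho
        self.lambda_ = float(lam)
        self.beta_ = X.T @ self.v_inv_y_
        self.X_train_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def solve_v(self, B: np.ndarray) -> np.ndarray:
        """V^-1 B for the fitted V = XX' + lambda I (used by accuracy formulas)."""
        check_is_fitted(self, "lambda_")
        return linalg.cho_solve(self._v_cho, np.asarray(B, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "beta_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.beta_.size:
            raise ValueError("X_new column count must match the fitted markers")
        return X @ self.beta_


def fit(X, y, lam: float) -> RRBLUP:
    """Fit RRBLUP at a fixed lambda (thin functional wrapper)."""
    return RRBLUP(alpha=lam, method="fixed").fit(X, y)


def predict(model: RRBLUP, X_new) -> np.ndarray:
    return model.predict(X_new)
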