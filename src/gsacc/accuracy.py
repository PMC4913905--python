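"""Exact theoretical accuracy of RRBLUP prediction and its estimators.

Conditionally on the training marker matrix X and training causal
matrix Q, the phenotypic accuracy of the ridge predictor
y_hat = x' X' V^-1 y (V = XX' + lambda I) for a random test individual
with markers x and causal genotype q is

    rho_RR = theta' E(q x') X' V^-1 Q theta
             / sqrt(sigma_e^2 E||x' X' V^-1||^2
                    + theta' Q' V^-1 X Var(x) X' V^-1 Q theta)
             / sqrt(sigma_G^2 + sigma_e^2).

The expectations over the test distribution are replaced by sample
averages over the realized test individuals (the plug-in estimators),
with the environmental variance taken at its known value.  The module
also provides the empirical (Pearson) accuracy, the oracle accuracy
(h for phenotypes, 1 for genetic values) and the independent-loci
closed forms of Daetwyler type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "AccuracyInputs",
    "AccuracyReport",
    "ridge_weights",
    "estimate_components",
    "theoretical_accuracy",
    "empirical_accuracy",
    "oracle_accuracy",
    "daetwyler_accuracy",
]


@dataclass
class AccuracyInputs:
    """Centered TRN/TST matrices and trait parameters for the accuracy formula."""

    X: np.ndarray          # nTRN x p centered TRN markers
    Q: np.ndarray          # nTRN x C centered TRN causal genotypes
    X_tst: np.ndarray      # nTST x p centered TST markers
    Q_tst: np.ndarray      # nTST x C centered TST causal genotypes
    theta: np.ndarray      # C fixed QTL effects
    lam: float             # ridge regularization parameter
    sigma_e2: float        # environmental variance (known / configured)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.X_tst = np.asarray(self.X_tst, dtype=float)
        self.Q_tst = np.asarray(self.Q_tst, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.X.shape[0] != self.Q.shape[0]:
            raise ValueError("TRN marker and causal matrices must share rows")
        if self.X_tst.shape[0] != self.Q_tst.shape[0]:
            raise ValueError("TST marker and causal matrices must share rows")
        if self.X.shape[1] != self.X_tst.shape[1]:
            raise ValueError("TRN/TST marker panels differ")
        if self.Q.shape[1] != self.theta.size:
            raise ValueError("theta length must match the causal matrix")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class AccuracyReport:
    rho_empirical: float | None
    rho_theoretical: float
    rho_oracle: float
    rho_tilde_oracle: float
    effective_dimension: float


def ridge_weights(X: np.ndarray, lam: float) -> np.ndarray:
    """The p x n matrix A = X' V^-1 = (X'X + lambda I)^-1 X'.

    For lambda > 0 the dual (n x n) system is solved; at lambda = 0 the
    primal normal matrix X'X must be invertible (p <= n, full column
    rank), which recovers the least-squares limit used by the
    independent-loci closed forms.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if lam > 0:
        V = X @ X.T + lam * np.eye(n)
        return linalg.cho_solve(linalg.cho_factor(V), X).T
    try:
        return linalg.cho_solve(linalg.cho_factor(X.T @ X), X.T)
    except linalg.LinAlgError:
        raise linalg.LinAlgError(
            "lambda = 0 requires X'X to be invertible") from None


def _component_terms(inputs: AccuracyInputs):
    """Shared plug-in quantities; avoids materializing Var(x) (p x p)."""
    m = inputs.X_tst.shape[0]
    if m < 2:
        raise ValueError("need at least 2 TST individuals")
    A = ridge_weights(inputs.X, inputs.lam)            # p x n
    R = inputs.X_tst @ A                               # nTST x nTRN rows x_i'X'V^-1
    comp_norm = float(np.mean(np.sum(R * R, axis=1)))
    g_trn = inputs.Q @ inputs.theta
    g_tst = inputs.Q_tst @ inputs.theta
    w = A @ g_trn                                      # X' V^-1 Q theta
    xw = inputs.X_tst @ w
    cross = float(g_tst @ xw / m)
    var_term = float(xw @ xw / m)                      # w' Var_hat(x) w
    sigma_g2 = float(np.mean((g_tst - g_tst.mean()) ** 2))
    return comp_norm, cross, var_term, sigma_g2, R


def estimate_components(inputs: AccuracyInputs):
    """The four plug-in estimators of the accuracy formula.

    Returns ``(comp_norm, cross, var_x, sigma_g2)``:
    (i) the TST average of ||x_i' X' V^-1||^2, (ii) the cross term
    theta' [mean q_i x_i'] X' V^-1 Q theta, (iii) the uncentered TST
    second-moment matrix (1/nTST) X_tst' X_tst estimating Var(x), and
    (iv) the TST empirical (mean-subtracted, 1/nTST) variance of
    q_i' theta estimating sigma_G^2.
    """
    comp_norm, cross, _, sigma_g2, _ = _component_terms(inputs)
    m = inputs.X_tst.shape[0]
    var_x = inputs.X_tst.T @ inputs.X_tst / m
    return comp_norm, cross, var_x, sigma_g2


def theoretical_accuracy(inputs: AccuracyInputs) -> float:
    """Plug-in value of the closed-form ridge accuracy rho_RR."""
    if inputs.sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    comp_norm, cross, var_term, sigma_g2, _ = _component_terms(inputs)
    denom_pred = inputs.sigma_e2 * comp_norm + var_term
    denom = np.sqrt(denom_pred) * np.sqrt(sigma_g2 + inputs.sigma_e2)
    if denom == 0.0:
        raise ZeroDivisionError("degenerate accuracy denominator")
    return float(cross / denom)


def empirical_accuracy(predictions: np.ndarray, truths: np.ndarray) -> float:
    """Pearson correlation between predicted and true values."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.size != truths.size or predictions.size < 3:
        raise ValueError("need at least 3 matching pairs")
    if np.ptp(predictions) == 0 or np.ptp(truths) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(predictions, truths)[0, 1])


def oracle_accuracy(h2: float) -> tuple[float, float]:
    """Accuracy with known QTLs: (rho_oracle, rho_tilde_oracle) = (h, 1)."""
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    return float(np.sqrt(h2)), 1.0


def daetwyler_accuracy(c_or_me: float, n_trn: int, h2: float) -> tuple[float, float]:
    """Independent-loci closed forms for C (or an effective count Me) loci.

    rho_tilde = sqrt[(h2/(1-h2)) / (C/nTRN + h2/(1-h2))] and
    rho = h * rho_tilde.  Substituting an effective number of segments
    for C gives the Me-based proxies.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie strictly between 0 and 1")
    if c_or_me <= 0 or n_trn <= 0:
        raise ValueError("counts must be positive")
    u = h2 / (1.0 - h2)
    rho_tilde = float(np.sqrt(u / (c_or_me / n_trn + u)))
    return rho_tilde, float(np.sqrt(h2) * rho_tilde)
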