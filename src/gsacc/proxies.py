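"""Accuracy proxies free of QTL parameters.

The QTL-free proxy replaces the unknown causal terms of the exact
accuracy with the effective dimension E||x' X' V^-1||^2, assuming each
QTL is in perfect LD with one marker:

    rho_pLD = h * sqrt[ (h^2/(1-h2)) / (E||x' X' V^-1||^2 + h^2/(1-h2)) ],

with an imperfect-LD extension for a constant marker-QTL LD of r^2.
Competing proxies substitute an effective number of independent
segments Me (from the effective population size Ne via the LD decay
curve, or from the effective number of independent tests M_LJ) into the
independent-loci closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .accuracy import AccuracyInputs, _component_terms

__all__ = [
    "LDSummary",
    "ProxySet",
    "new_proxy",
    "new_proxy_imperfect",
    "effective_dimension",
    "pairwise_ld",
    "estimate_ne",
    "me_formulas",
    "m_li_ji",
    "proxy_mse",
]


@dataclass
class LDSummary:
    """Pairwise LD observations and the Ne estimate fitted from them."""

    distances: np.ndarray   # Morgans
    r2: np.ndarray
    ne_hat: float
    L: float = 1.0          # genome length, Morgans
    l: float = 1.0          # average chromosome length, Morgans


@dataclass
class ProxySet:
    rho_pld: float
    me1: float
    me2: float
    me3: float
    m_lj: float
    effective_dimension: float
    rho_me1: float
    rho_me2: float
    rho_me3: float
    rho_mlj: float
    ne_hat: float


def _odds(h2: float) -> float:
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie strictly between 0 and 1")
    return h2 / (1.0 - h2)


def new_proxy(h2: float, effective_term: float) -> float:
    """QTL-free accuracy proxy from the effective term E||x' X' V^-1||^2."""
    if effective_term < 0:
        raise ValueError("effective_term must be non-negative")
    u = _odds(h2)
    return float(np.sqrt(h2) * np.sqrt(u / (effective_term + u)))


def new_proxy_imperfect(h2: float, effective_term: float, r2: float) -> float:
    """Imperfect-LD proxy: constant LD r^2 between each QTL and its marker.

    rho = r^2 * h * sqrt[(h2/(1-h2)) / (E||x'X'V^-1||^2 + r^2 h2/(1-h2))];
    r^2 = 1 recovers the perfect-LD proxy.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must lie in [0, 1]")
    if effective_term < 0:
        raise ValueError("effective_term must be non-negative")
    u = _odds(h2)
    if r2 == 0.0:
        return 0.0
    return float(r2 * np.sqrt(h2) * np.sqrt(u / (effective_term + r2 * u)))


def effective_dimension(X: np.ndarray, lam: float, X_tst: np.ndarray) -> float:
    """nTRN * (TST average of ||x' X' V^-1||^2).

    This is the quantity that should replace the effective number of
    independent loci in the independent-loci accuracy formula.
    """
    X = np.asarray(X, dtype=float)
    X_tst = np.asarray(X_tst, dtype=float)
    dummy = np.zeros((X.shape[0], 1))
    dummy_t = np.zeros((X_tst.shape[0], 1))
    inputs = AccuracyInputs(X, dummy, X_tst, dummy_t, np.zeros(1), lam, 1.0)
    comp_norm = _component_terms(inputs)[0]
    return X.shape[0] * comp_norm


def pairwise_ld(genotypes: np.ndarray, positions: np.ndarray,
                max_pairs: int | None = None,
                rng: np.random.Generator | None = None):
    """All pairwise (distance, r^2) values between marker columns.

    ``max_pairs`` subsamples pairs (without replacement) to bound the
    cost on dense panels.
    """
    G = np.asarray(genotypes, dtype=float)
    positions = np.asarray(positions, dtype=float)
    corr = np.corrcoef(G, rowvar=False)
    iu, ju = np.triu_indices(G.shape[1], k=1)
    r2 = corr[iu, ju] ** 2
    dist = np.abs(positions[ju] - positions[iu])
    good = np.isfinite(r2)
    dist, r2 = dist[good], r2[good]
    if max_pairs is not None and dist.size > max_pairs:
        rng = rng if rng is not None else np.random.default_rng(0)
        keep = rng.choice(dist.size, size=max_pairs, replace=False)
        dist, r2 = dist[keep], r2[keep]
    return dist, r2


def estimate_ne(distances: np.ndarray, r2: np.ndarray, n_sample: int,
                curve: str = "hill-weir", a: float = 1.0,
                b: float = 4.0) -> float:
    """Effective population size from the LD decay curve.

    Nonlinear least-squares fit of observed r^2 against an expected
    decay curve in the recombination intensity C = b*Ne*c (c = map
    distance in Morgans), with the 1/n sample-size correction:

    - ``curve="hill-weir"`` (default): the Hill & Weir (1988) drift
      expectation E[r^2] = (10+C)/((2+C)(11+C)) + 1/n;
    - ``curve="sved"``: the Sved-type form E[r^2] = 1/(a+C) + 1/n.

    ``b=4`` is the standard (diploid-rate) convention; ``b=2`` is the
    haploid-rate variant.
    """
    distances = np.asarray(distances, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if distances.size < 10 or np.unique(distances).size < 2:
        raise ValueError("need >= 10 LD pairs spanning distinct distances")

    if curve == "hill-weir":
        def model(c, ne):
            C = b * ne * c
            return (10.0 + C) / ((2.0 + C) * (11.0 + C)) + 1.0 / n_sample
    elif curve == "sved":
        def model(c, ne):
            return 1.0 / (a + b * ne * c) + 1.0 / n_sample
    else:
        raise ValueError(f"unknown LD decay curve {curve!r}")

    try:
        popt, _ = optimize.curve_fit(model, distances, r2, p0=[50.0],
                                     bounds=(1e-6, 1e8), maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError(f"Ne fit did not converge: {err}") from None
    ne_hat = float(popt[0])
    if ne_hat >= 1e6:
        raise RuntimeError("Ne estimate diverged: r^2 shows no decay "
                           "with distance (all near the 1/n noise floor)")
    return ne_hat


def me_formulas(ne: float, L: float, l: float) -> tuple[float, float, float]:
    """Effective numbers of independent chromosome segments.

    Me1 = 2*Ne*L / ln(4*Ne*l), Me2 = 2*Ne*L / ln(2*Ne*l),
    Me3 = 2*Ne*L / ln(Ne*l); natural logarithms, L the genome length and
    l the average chromosome length (Morgans).
    """
    if L <= 0 or l <= 0:
        raise ValueError("L and l must be positive")
    if ne * l <= 1.0:
        raise ValueError("Ne*l must exceed 1 for the log denominators")
    return tuple(2.0 * ne * L / np.log(k * ne * l) for k in (4.0, 2.0, 1.0))


def m_li_ji(genotypes: np.ndarray, positions: np.ndarray | None = None,
            n_splits: int = 1) -> float:
    """Effective number of independent tests (Li & Ji eigenvalue rule).

    Eigenvalues lam_i of the marker correlation matrix over the pooled
    TRN+TST genotypes give Meff = sum_i [1(lam_i >= 1) + (lam_i -
    floor(lam_i))].  The rule requires p < n, so dense panels are split
    into ``n_splits`` equal-width position intervals and the per-split
    counts are summed.
    """
    G = np.asarray(genotypes, dtype=float)
    n, p = G.shape
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if n_splits == 1:
        blocks = [np.arange(p)]
    else:
        if positions is None:
            raise ValueError("positions are required to split the chromosome")
        positions = np.asarray(positions, dtype=float)
        edges = np.linspace(positions.min(), positions.max(), n_splits + 1)
        which = np.clip(np.searchsorted(edges, positions, side="right") - 1,
                        0, n_splits - 1)
        blocks = [np.nonzero(which == k)[0] for k in range(n_splits)]
    total = 0.0
    for block in blocks:
        if block.size == 0:
            continue
        if block.size >= n:
            raise ValueError(
                f"{block.size} markers in one split but only {n} individuals; "
                "increase n_splits (the eigenvalue rule requires p < n)")
        corr = np.corrcoef(G[:, block], rowvar=False)
        if block.size == 1:
            corr = np.atleast_2d(corr)
        eig = np.linalg.eigvalsh(corr)
        eig = np.where(eig < 1e-10, 0.0, eig)
        total += float(np.sum((eig >= 1.0) + (eig - np.floor(eig))))
    return total


def proxy_mse(proxy_values: np.ndarray, empirical_values: np.ndarray) -> float:
    """Mean squared error of per-architecture proxy means vs empirical means."""
    proxy_values = np.asarray(proxy_values, dtype=float)
    empirical_values = np.asarray(empirical_values, dtype=float)
    if proxy_values.shape != empirical_values.shape:
        raise ValueError("vectors must have equal length")
    return float(np.mean((proxy_values - empirical_values) ** 2))
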