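"""Sparse causal trait model and heritability.

The quantitative trait follows Y = Q theta + e, where Q is the centered
incidence matrix at the C causal loci (QTLs), theta the vector of fixed
QTL effects and e ~ N(0, sigma_e^2 I) the environmental noise.  The
narrow-sense heritability is h^2 = sigma_G^2 / (sigma_G^2 + sigma_e^2)
with sigma_G^2 = theta' Var(q) theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TraitArchitecture",
    "PhenotypeSet",
    "qtl_scenarios",
    "QTL_SCENARIO_NAMES",
    "center_columns",
    "simulate_phenotypes",
    "estimate_heritability",
]


@dataclass(frozen=True)
class TraitArchitecture:
    """Positions (Morgans), fixed effects theta and environmental variance."""

    qtl_positions: np.ndarray
    effects: np.ndarray
    sigma_e2: float = 1.0
    name: str = ""

    def __post_init__(self):
        pos = np.asarray(self.qtl_positions, dtype=float)
        eff = np.asarray(self.effects, dtype=float)
        if pos.size != eff.size or pos.size < 1:
            raise ValueError("need matching, non-empty positions and effects")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")
        object.__setattr__(self, "qtl_positions", pos)
        object.__setattr__(self, "effects", eff)

    @property
    def n_qtl(self) -> int:
        return self.effects.size


@dataclass
class PhenotypeSet:
    y: np.ndarray                # centered phenotypes
    genetic_values: np.ndarray   # q_i' theta
    e: np.ndarray                # environmental residuals


QTL_SCENARIO_NAMES = ("two_qtl", "hundred_qtl", "mixture_a", "mixture_b", "mixture_c")

# QTL grid for the 100-QTL and mixture scenarios: one locus per centimorgan.
_CM_GRID = np.round(np.arange(100) * 0.01, 10)
_MIX_SMALL = np.array([p for p in _CM_GRID if p not in (0.03, 0.80)])


def _mixture(name, big_effects, small_effect):
    positions = np.concatenate([[0.03, 0.80], _MIX_SMALL])
    effects = np.concatenate([big_effects, np.full(_MIX_SMALL.size, small_effect)])
    order = np.argsort(positions, kind="stable")
    return TraitArchitecture(positions[order], effects[order], 1.0, name)


_CUSTOM_SCENARIOS: dict[str, TraitArchitecture] = {}


def register_scenario(name: str, positions_cm, effects,
                      sigma_e2: float = 1.0) -> TraitArchitecture:
    """Register a user-defined QTL architecture (positions in cM).

    Registered names become available to ``qtl_scenarios`` and hence to
    experiment configs; built-in names cannot be overridden.
    """
    if name in QTL_SCENARIO_NAMES:
        raise ValueError(f"cannot override built-in scenario {name!r}")
    arch = TraitArchitecture(np.asarray(positions_cm, dtype=float) / 100.0,
                             effects, sigma_e2, name)
    _CUSTOM_SCENARIOS[name] = arch
    return arch


def qtl_scenarios(name: str | None = None):
    """Named QTL architectures of the simulation study (sigma_e^2 = 1).

    ``two_qtl``: 2 QTLs at 3 and 80 cM with effects +1 and -2.
    ``hundred_qtl``: 100 QTLs every centimorgan, common effect +0.15.
    ``mixture_a/b/c``: two large QTLs at 3 and 80 cM (+0.5/-0.6, +1/-0.7,
    +2/-2) plus 98 small QTLs of common effect (+0.07, +0.1, +0.1) on the
    remaining centimorgan grid points.
    """
    scenarios = {
        "two_qtl": TraitArchitecture([0.03, 0.80], [1.0, -2.0], 1.0, "two_qtl"),
        "hundred_qtl": TraitArchitecture(_CM_GRID, np.full(100, 0.15), 1.0,
                                         "hundred_qtl"),
        "mixture_a": _mixture("mixture_a", [0.5, -0.6], 0.07),
        "mixture_b": _mixture("mixture_b", [1.0, -0.7], 0.1),
        "mixture_c": _mixture("mixture_c", [2.0, -2.0], 0.1),
    }
    scenarios.update(_CUSTOM_SCENARIOS)
    if name is None:
        return scenarios
    try:
        return scenarios[name]
    except KeyError:
        raise ValueError(f"unknown QTL scenario {name!r}; "
                         f"choose from {tuple(scenarios)}") from None


def center_columns(matrix: np.ndarray,
                   reference_means: np.ndarray | None = None) -> np.ndarray:
    """Subtract per-column reference means (own means if not given)."""
    matrix = np.asarray(matrix, dtype=float)
    if reference_means is None:
        reference_means = matrix.mean(axis=0)
    reference_means = np.asarray(reference_means, dtype=float)
    if reference_means.shape != (matrix.shape[1],):
        raise ValueError("reference_means must have one entry per column")
    return matrix - reference_means


def simulate_phenotypes(Q: np.ndarray, arch: TraitArchitecture,
                        rng: np.random.Generator) -> PhenotypeSet:
    """Draw phenotypes y_i = q_i' theta + e_i, e_i iid N(0, sigma_e^2).

    ``Q`` is the centered QTL incidence matrix; phenotypes are returned
    centered (their mean subtracted), matching the convention that
    genotypes and phenotypes enter the predictor centered.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[1] != arch.n_qtl:
        raise ValueError("Q column count must equal the number of QTLs")
    g = Q @ arch.effects
    e = rng.normal(0.0, np.sqrt(arch.sigma_e2), size=Q.shape[0])
    y = g + e
    return PhenotypeSet(y=y - y.mean(), genetic_values=g, e=e)


def estimate_heritability(genetic_values: np.ndarray, sigma_e2: float) -> float:
    """h^2 = Var_hat(q'theta) / (Var_hat(q'theta) + sigma_e2).

    The empirical (unbiased, n-1 denominator) variance of the genetic
    values over the pooled TRN+TST sample is used, with the true
    environmental variance in the denominator.
    """
    g = np.asarray(genetic_values, dtype=float)
    if g.size < 2:
        raise ValueError("need at least 2 genetic values")
    v = float(np.var(g, ddof=1))
    if v == 0.0:
        return 0.0
    return v / (v + sigma_e2)
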