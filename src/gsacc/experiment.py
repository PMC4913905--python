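"""Simulation-study orchestration.

Runs the full benchmarking design: for each architecture (marker
density x generations x QTL scenario x training-set size) and each
replicate, simulate a population, split into training (TRN, including a
full-sib family) and test (TST) sets, filter markers, generate
phenotypes, fit RRBLUP, and compute the empirical accuracy, the
theoretical accuracy and all proxies.  Supports the fixed-TRN-matrix
mode (only TST and phenotypes are redrawn across replicates), the
QTL-removed (imperfect LD) mode, and TST populations evolved for extra
generations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import proxies as proxies_mod
from .accuracy import (AccuracyInputs, _component_terms, daetwyler_accuracy,
                       empirical_accuracy, theoretical_accuracy)
from .ridge import RRBLUP, estimate_lambda_h2
from .simulate import (GeneticMap, HaploidPopulation, branch_tst, evolve,
                       filter_markers, make_founders, make_full_sibs,
                       _random_offspring)
from .traits import (TraitArchitecture, center_columns, estimate_heritability,
                     qtl_scenarios)

logger = logging.getLogger(__name__)

__all__ = [
    "SimArchitecture",
    "ExperimentConfig",
    "default_grid",
    "replicate_rng",
    "run_replicate",
    "run_architecture",
    "run_fixed_trn",
    "run_grid",
    "summarize",
    "PROXY_COLUMNS",
]

# proxy columns compared against the empirical accuracy in the MSE table
PROXY_COLUMNS = ("rho_theoretical", "rho_pld", "rho_me1", "rho_me2", "rho_me3",
                 "rho_mlj")


@dataclass(frozen=True)
class SimArchitecture:
    """One cell of the simulation grid."""

    n_markers: int
    n_generations: int
    n_trn: int
    qtl_scenario: str
    n_tst: int = 100

    def __post_init__(self):
        if self.n_trn % 5 != 0:
            raise ValueError("n_trn must decompose as pop_size + pop_size/4")

    @property
    def pop_size(self) -> int:
        return 4 * self.n_trn // 5

    @property
    def n_fullsibs(self) -> int:
        return self.n_trn // 5

    @property
    def label(self) -> str:
        return (f"{self.qtl_scenario}/g{self.n_generations}"
                f"/m{self.n_markers}/n{self.n_trn}")


@dataclass
class ExperimentConfig:
    """Run-level options shared across architectures."""

    n_replicates: int = 100
    lambda_route: str = "reml"          # reml | h2 | h2_misspecified_0.9
    trn_matrix_mode: str = "vary"       # vary | fixed
    qtl_in_markers: str = "included"    # included | removed
    tst_extra_generations: int = 0
    centering: str = "pooled"           # pooled | trn
    compute_proxies: bool = True
    master_seed: int = 0
    max_ld_pairs: int = 100_000
    max_failures_frac: float = 0.05

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.lambda_route not in ("reml", "h2", "h2_misspecified_0.9"):
            raise ValueError(f"unknown lambda route {self.lambda_route!r}")
        if self.trn_matrix_mode not in ("vary", "fixed"):
            raise ValueError("trn_matrix_mode must be 'vary' or 'fixed'")
        if self.qtl_in_markers not in ("included", "removed"):
            raise ValueError("qtl_in_markers must be 'included' or 'removed'")


def default_grid(n_trn_values=(500, 1000)) -> list[SimArchitecture]:
    """The 48-architecture grid of the simulation study."""
    return [SimArchitecture(m, g, n, q)
            for q in ("two_qtl", "hundred_qtl")
            for g in (30, 50, 70)
            for m in (100, 1000, 5000, 10000)
            for n in n_trn_values]


def replicate_rng(config: ExperimentConfig, arch_index: int,
                  replicate: int) -> np.random.Generator:
    """Independent, reproducible stream per (architecture, replicate)."""
    return np.random.default_rng(
        np.random.SeedSequence(config.master_seed,
                               spawn_key=(arch_index, replicate)))


_replicate_rng = replicate_rng


def _qtl_indices(gmap: GeneticMap, trait: TraitArchitecture) -> np.ndarray:
    idx = np.array([gmap.nearest_locus(p) for p in trait.qtl_positions])
    if np.unique(idx).size != idx.size:
        raise ValueError("QTL positions collide on the marker grid")
    return idx


def _simulate_trn(arch: SimArchitecture, gmap: GeneticMap,
                  rng: np.random.Generator):
    """Penultimate population plus the training matrix (pool + full sibs)."""
    founders = make_founders(gmap)
    pen = evolve(founders, arch.n_generations - 1, arch.pop_size, rng)
    pool = HaploidPopulation(_random_offspring(pen, arch.pop_size, rng),
                             gmap, pen.generation + 1)
    sibs = make_full_sibs(pool, arch.n_fullsibs, rng)
    trn_alleles = np.vstack([pool.alleles, sibs.alleles])
    return pen, trn_alleles


def _mlj_splits(n_markers: int) -> int:
    # chromosome split rule keeping p < n per block on dense panels
    if n_markers >= 5000:
        return 3
    if n_markers >= 1000:
        return 2
    return 1


def evaluate_split(arch: SimArchitecture, config: ExperimentConfig,
                   gmap: GeneticMap, trn_alleles: np.ndarray,
                   tst_alleles: np.ndarray, rng: np.random.Generator) -> dict:
    """Phenotypes, RRBLUP fit and every accuracy/proxy for one TRN/TST pair."""
    trait = qtl_scenarios(arch.qtl_scenario)
    qtl_idx = _qtl_indices(gmap, trait)
    n_trn = trn_alleles.shape[0]

    kept = filter_markers(trn_alleles)
    pooled = np.vstack([trn_alleles, tst_alleles]).astype(float)
    ref = (pooled.mean(axis=0) if config.centering == "pooled"
           else trn_alleles.mean(axis=0))
    centered = center_columns(pooled, ref)

    Q_all = centered[:, qtl_idx]
    marker_cols = kept
    if config.qtl_in_markers == "removed":
        marker_cols = kept[~np.isin(kept, qtl_idx)]
    X_all = centered[:, marker_cols]
    X_trn, X_tst = X_all[:n_trn], X_all[n_trn:]
    Q_trn, Q_tst = Q_all[:n_trn], Q_all[n_trn:]

    g_all = Q_all @ trait.effects
    e_all = rng.normal(0.0, np.sqrt(trait.sigma_e2), size=g_all.size)
    y_all = g_all + e_all
    y_all = y_all - y_all.mean()
    y_trn, y_tst = y_all[:n_trn], y_all[n_trn:]

    h2_hat = estimate_heritability(g_all, trait.sigma_e2)

    if config.lambda_route == "reml":
        model = RRBLUP(method="reml").fit(X_trn, y_trn)
    else:
        h2_for_lambda = h2_hat * (0.9 if config.lambda_route ==
                                  "h2_misspecified_0.9" else 1.0)
        lam = estimate_lambda_h2(X_trn, h2_for_lambda)
        model = RRBLUP(alpha=lam, method="fixed").fit(X_trn, y_trn)

    y_hat = model.predict(X_tst)
    rho_emp = empirical_accuracy(y_hat, y_tst)
    rho_emp_gen = empirical_accuracy(y_hat, Q_tst @ trait.effects)

    inputs = AccuracyInputs(X_trn, Q_trn, X_tst, Q_tst, trait.effects,
                            model.lambda_, trait.sigma_e2)
    comp_norm = _component_terms(inputs)[0]
    rho_theo = theoretical_accuracy(inputs)
    eff_dim = n_trn * comp_norm

    row = {
        "architecture": arch.label,
        "n_markers": arch.n_markers,
        "n_generations": arch.n_generations,
        "n_trn": n_trn,
        "qtl_scenario": arch.qtl_scenario,
        "n_kept_markers": int(kept.size),
        "h2_hat": h2_hat,
        "lambda": model.lambda_,
        "rho_empirical": rho_emp,
        "rho_empirical_genotypic": rho_emp_gen,
        "rho_theoretical": rho_theo,
        "rho_oracle": float(np.sqrt(h2_hat)),
        "effective_dimension": eff_dim,
    }

    if config.compute_proxies:
        row["rho_pld"] = proxies_mod.new_proxy(h2_hat, comp_norm)
        dist, r2 = proxies_mod.pairwise_ld(
            X_trn, gmap.positions[marker_cols],
            max_pairs=config.max_ld_pairs, rng=rng)
        ne_hat = proxies_mod.estimate_ne(dist, r2, n_sample=n_trn)
        me1, me2, me3 = proxies_mod.me_formulas(ne_hat, gmap.chrom_length,
                                                gmap.avg_chrom_length)
        for name, me in (("me1", me1), ("me2", me2), ("me3", me3)):
            row[f"rho_{name}"] = daetwyler_accuracy(me, n_trn, h2_hat)[1]
        m_lj = proxies_mod.m_li_ji(X_all, gmap.positions[marker_cols],
                                   n_splits=_mlj_splits(arch.n_markers))
        row["rho_mlj"] = daetwyler_accuracy(m_lj, n_trn, h2_hat)[1]
        row.update(ne_hat=ne_hat, me1=me1, me2=me2, me3=me3, m_lj=m_lj)
    return row


def run_replicate(arch: SimArchitecture, config: ExperimentConfig,
                  rng: np.random.Generator) -> dict:
    """One full varying-TRN replicate: simulate, split, fit, evaluate."""
    gmap = GeneticMap.equally_spaced(arch.n_markers)
    pen, trn_alleles = _simulate_trn(arch, gmap, rng)
    tst = branch_tst(pen, config.tst_extra_generations, arch.n_tst, rng)
    return evaluate_split(arch, config, gmap, trn_alleles, tst.alleles, rng)


def run_architecture(arch: SimArchitecture, config: ExperimentConfig,
                     arch_index: int = 0) -> pd.DataFrame:
    """All replicates of one architecture (vary or fixed TRN mode)."""
    if config.trn_matrix_mode == "fixed":
        return run_fixed_trn(arch, config, arch_index)
    rows = []
    for r in range(config.n_replicates):
        rng = _replicate_rng(config, arch_index, r)
        rows.append(_guarded(run_replicate, arch, config, rng, replicate=r))
    return _collect(rows, config)


def run_fixed_trn(arch: SimArchitecture, config: ExperimentConfig,
                  arch_index: int = 0) -> pd.DataFrame:
    """Fixed-TRN mode: one TRN population; TST and phenotypes redrawn."""
    base_rng = _replicate_rng(config, arch_index, 2**20)
    gmap = GeneticMap.equally_spaced(arch.n_markers)
    pen, trn_alleles = _simulate_trn(arch, gmap, base_rng)
    rows = []
    for r in range(config.n_replicates):
        rng = _replicate_rng(config, arch_index, r)

        def one(arch, config, rng):
            tst = branch_tst(pen, config.tst_extra_generations, arch.n_tst, rng)
            return evaluate_split(arch, config, gmap, trn_alleles,
                                  tst.alleles, rng)

        rows.append(_guarded(one, arch, config, rng, replicate=r))
    return _collect(rows, config)


def _guarded(fn, arch, config, rng, replicate):
    try:
        row = fn(arch, config, rng)
        row["replicate"] = replicate
        row["failed_stage"] = ""
        logger.info("arch=%s replicate=%d seed=%d stage=done rho_emp=%.4f",
                    arch.label, replicate, config.master_seed,
                    row["rho_empirical"])
        return row
    except Exception as err:  # noqa: BLE001 - a failed replicate must not kill the run
        logger.warning("arch=%s replicate=%d seed=%d stage=failed error=%s",
                       arch.label, replicate, config.master_seed, err)
        return {"architecture": arch.label, "replicate": replicate,
                "failed_stage": f"{type(err).__name__}: {err}"}


def _collect(rows: list[dict], config: ExperimentConfig) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    n_failed = int((df["failed_stage"] != "").sum())
    if n_failed > config.max_failures_frac * len(df):
        raise RuntimeError(f"{n_failed}/{len(df)} replicates failed")
    return df


def run_grid(architectures: list[SimArchitecture],
             config: ExperimentConfig) -> pd.DataFrame:
    """Replicate table over a list of architectures."""
    frames = [run_architecture(arch, config, arch_index=i)
              for i, arch in enumerate(architectures)]
    return pd.concat(frames, ignore_index=True)


def summarize(rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-architecture means/variances and the proxy MSE table.

    The MSE of each proxy is the mean over architectures of the squared
    difference between the proxy's per-architecture mean and the
    empirical accuracy's per-architecture mean.
    """
    ok = rows[rows["failed_stage"] == ""] if "failed_stage" in rows else rows
    if ok.empty:
        raise ValueError("no successful replicates to summarize")
    numeric = ok.select_dtypes("number").columns.difference(["replicate"])
    grouped = ok.groupby("architecture")[list(numeric)]
    summary = grouped.agg(["mean", "var"])
    means = grouped.mean()
    mse_rows = {}
    for col in PROXY_COLUMNS:
        if col in means:
            mse_rows[col] = proxies_mod.proxy_mse(
                means[col].to_numpy(), means["rho_empirical"].to_numpy())
    mse = pd.DataFrame.from_dict(mse_rows, orient="index", columns=["mse"])
    return summary, mse
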