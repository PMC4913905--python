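"""Experiment runner: determinism, modes, summaries."""

import numpy as np
import pandas as pd
import pytest

from gsacc.experiment import (ExperimentConfig, SimArchitecture, default_grid,
                              _replicate_rng, run_architecture, run_fixed_trn,
                              run_grid, run_replicate, summarize)

LIGHT = SimArchitecture(100, 10, 500, "two_qtl")


def light_config(**kw):
    base = dict(n_replicates=2, compute_proxies=False, master_seed=5,
                lambda_route="h2")
    base.update(kw)
    return ExperimentConfig(**base)


class TestArchitecture:
    def test_derived_counts(self):
        arch = SimArchitecture(1000, 50, 500, "two_qtl")
        assert arch.pop_size == 400
        assert arch.n_fullsibs == 100
        assert arch.pop_size + arch.n_fullsibs == arch.n_trn

    def test_grid_size(self):
        assert len(default_grid()) == 48

    def test_invalid_trn_rejected(self):
        with pytest.raises(ValueError):
            SimArchitecture(100, 30, 501, "two_qtl")


class TestReplicates:
    def test_same_seed_identical_rows(self):
        config = light_config()
        r1 = run_replicate(LIGHT, config, _replicate_rng(config, 0, 0))
        r2 = run_replicate(LIGHT, config, _replicate_rng(config, 0, 0))
        assert r1 == r2

    def test_different_replicates_differ(self):
        config = light_config()
        r1 = run_replicate(LIGHT, config, _replicate_rng(config, 0, 0))
        r2 = run_replicate(LIGHT, config, _replicate_rng(config, 0, 1))
        assert r1["rho_empirical"] != r2["rho_empirical"]

    def test_replicate_streams_never_collide_across_architectures(self):
        config = light_config()
        draws = {
            (a, r): _replicate_rng(config, a, r).integers(0, 2**63)
            for a in range(10) for r in range(10)
        }
        assert len(set(draws.values())) == len(draws)

    def test_row_has_core_fields(self):
        config = light_config(compute_proxies=True)
        row = run_replicate(LIGHT, config, _replicate_rng(config, 0, 0))
        for key in ("rho_empirical", "rho_theoretical", "h2_hat", "lambda",
                    "effective_dimension", "rho_pld", "rho_me1", "rho_mlj"):
            assert key in row
        assert -1 <= row["rho_theoretical"] <= 1
        assert -1 <= row["rho_empirical"] <= 1

    def test_qtl_removed_drops_causal_columns(self):
        config = light_config(qtl_in_markers="removed")
        row = run_replicate(LIGHT, config, _replicate_rng(config, 0, 0))
        config_inc = light_config()
        row_inc = run_replicate(LIGHT, config_inc, _replicate_rng(config_inc, 0, 0))
        # same simulation, two fewer marker columns in the predictor
        assert row["n_kept_markers"] == row_inc["n_kept_markers"]
        assert row["lambda"] < row_inc["lambda"]  # fewer columns, smaller sum X^2


class TestFixedTrnMode:
    def test_reproducible_and_tst_varies(self):
        config = light_config(trn_matrix_mode="fixed", n_replicates=3)
        df1 = run_fixed_trn(LIGHT, config)
        df2 = run_fixed_trn(LIGHT, config)
        pd.testing.assert_frame_equal(df1, df2)
        assert df1["rho_empirical"].nunique() == 3
        # TRN panel fixed -> identical filtered marker count in every row
        assert df1["n_kept_markers"].nunique() == 1

    def test_effective_dimension_grows_with_tst_generations(self):
        """Evolving only the TST population inflates the effective
        dimension of the prediction problem (TRN held at its generation)."""
        arch = SimArchitecture(100, 30, 500, "two_qtl")
        means = []
        for extra in (0, 40):
            config = light_config(trn_matrix_mode="fixed", n_replicates=4,
                                  tst_extra_generations=extra, master_seed=21)
            df = run_fixed_trn(arch, config)
            means.append(df["effective_dimension"].mean())
        assert means[1] > means[0]


class TestLambdaRoutes:
    def test_route_insensitivity_of_theoretical_accuracy(self):
        """REML- and heritability-based lambda give matching mean accuracy
        on paired replicates."""
        arch = SimArchitecture(100, 30, 500, "two_qtl")
        means = {}
        for route in ("reml", "h2"):
            config = light_config(lambda_route=route, n_replicates=8,
                                  master_seed=17)
            df = run_architecture(arch, config)
            means[route] = df["rho_theoretical"].mean()
        assert abs(means["reml"] - means["h2"]) < 0.03

    def test_misspecified_h2_inflates_lambda_only(self):
        config_true = light_config(master_seed=17)
        config_mis = light_config(master_seed=17,
                                  lambda_route="h2_misspecified_0.9")
        row_true = run_replicate(LIGHT, config_true,
                                 _replicate_rng(config_true, 0, 0))
        row_mis = run_replicate(LIGHT, config_mis,
                                _replicate_rng(config_mis, 0, 0))
        # under-stated heritability means stronger shrinkage
        assert row_mis["lambda"] > row_true["lambda"]
        assert row_mis["h2_hat"] == row_true["h2_hat"]


class TestHeritabilityTrend:
    def test_polygenic_h2_declines_with_generations(self):
        """Drift erodes genetic variance: the 100-QTL trait loses
        heritability as the population keeps mating (0.75 -> 0.57
        pattern)."""
        from gsacc.simulate import GeneticMap, evolve, make_founders
        from gsacc.traits import (center_columns, estimate_heritability,
                                  qtl_scenarios)

        arch = qtl_scenarios("hundred_qtl")
        gmap = GeneticMap(arch.qtl_positions)
        means = []
        for g in (30, 70):
            vals = []
            for rep in range(15):
                rng = np.random.default_rng(3000 + 100 * g + rep)
                pop = evolve(make_founders(gmap), g, 400, rng)
                Q = center_columns(pop.alleles.astype(float))
                vals.append(estimate_heritability(Q @ arch.effects, 1.0))
            means.append(np.mean(vals))
        assert means[0] > means[1]
        assert 0.6 < means[0] < 0.9   # ~0.75 reference level
        assert 0.4 < means[1] < 0.75  # ~0.57 reference level


class TestCustomScenarios:
    def test_registered_scenario_runs_end_to_end(self):
        from gsacc.traits import register_scenario
        register_scenario("custom_three", [10, 50, 90], [1.0, -1.0, 0.5])
        arch = SimArchitecture(100, 10, 500, "custom_three")
        config = light_config()
        row = run_replicate(arch, config, _replicate_rng(config, 0, 0))
        assert -1 <= row["rho_theoretical"] <= 1

    def test_builtin_override_rejected(self):
        from gsacc.traits import register_scenario
        with pytest.raises(ValueError):
            register_scenario("two_qtl", [1], [1.0])


class TestSummaries:
    def test_mean_recomputable_from_rows(self):
        config = light_config(n_replicates=3, compute_proxies=True)
        rows = run_architecture(LIGHT, config)
        summary, mse = summarize(rows)
        direct = rows["rho_empirical"].mean()
        assert summary.loc[LIGHT.label, ("rho_empirical", "mean")] == direct
        assert set(mse.index) >= {"rho_theoretical", "rho_pld", "rho_mlj"}

    def test_identical_proxy_gives_zero_mse(self):
        rows = pd.DataFrame({
            "architecture": ["a", "a"],
            "failed_stage": ["", ""],
            "replicate": [0, 1],
            "rho_empirical": [0.5, 0.7],
            "rho_theoretical": [0.5, 0.7],
        })
        _, mse = summarize(rows)
        assert mse.loc["rho_theoretical", "mse"] == 0.0

    def test_grid_concatenates_architectures(self):
        archs = [LIGHT, SimArchitecture(100, 10, 500, "hundred_qtl")]
        config = light_config()
        rows = run_grid(archs, config)
        assert rows["architecture"].nunique() == 2
        assert len(rows) == 4

    def test_all_failed_rejected(self):
        rows = pd.DataFrame({"architecture": ["a"], "failed_stage": ["boom"],
                             "replicate": [0]})
        with pytest.raises(ValueError):
            summarize(rows)
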