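"""PGLS fitting: OLS limits, brute-force GLS agreement, λ profiling,
independent-contrasts identity, and batch fitting."""

import numpy as np
import pandas as pd
import pytest

from phyloallometry import (NumericalError, PhyloTree, SimulationConfig,
                            TraitTable, ValidationError, allometry_table,
                            fit_pgls, profile_lambda,
                            simulate_allometric_traits, simulate_tree)
from conftest import ols_slope_intercept


def brute_force_gls(tree, traits, response, predictor, lam):
    """Explicit-inversion GLS oracle, independent of the fit path."""
    order = sorted(set(tree.tip_labels) & set(traits.species))
    _, C = tree.shared_path_matrix(order=order)
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    y = np.log10(traits.df.loc[order, response].to_numpy(float))
    x = np.log10(traits.df.loc[order, predictor].to_numpy(float))
    X = np.column_stack([np.ones_like(x), x])
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return beta[1], beta[0]


class TestPglsBasics:
    def test_star_tree_equals_ols_any_lambda(self, star_tree_newick):
        tree = PhyloTree.from_newick(star_tree_newick)
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 3, 12)
        y = 0.5 + 0.8 * x + rng.normal(0, 0.1, 12)
        traits = TraitTable(pd.DataFrame(
            {"species": tree.tip_labels, "p": 10.0 ** x, "r": 10.0 ** y}))
        slope_ols, int_ols = ols_slope_intercept(x, y)
        for lam in (0.0, 0.5, 1.0):
            fit = fit_pgls(tree, traits, "r", "p", lam=lam)
            assert fit.slope == pytest.approx(slope_ols, abs=1e-10)
            assert fit.intercept == pytest.approx(int_ols, abs=1e-10)

    def test_lambda_zero_equals_ols_on_any_ultrametric_tree(self):
        cfg = SimulationConfig(seed=5, n_tips=15)
        tree = simulate_tree(cfg)
        traits = simulate_allometric_traits(tree, cfg)
        fit = fit_pgls(tree, traits, cfg.response_name, cfg.predictor_name,
                       lam=0.0)
        slope_ols, int_ols = ols_slope_intercept(fit.x, fit.y)
        assert fit.slope == pytest.approx(slope_ols, abs=1e-10)
        assert fit.intercept == pytest.approx(int_ols, abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_gls(self, seed):
        cfg = SimulationConfig(seed=seed, n_tips=8)
        tree = simulate_tree(cfg)
        traits = simulate_allometric_traits(tree, cfg)
        fit = fit_pgls(tree, traits, cfg.response_name, cfg.predictor_name,
                       lam="ML")
        slope_bf, int_bf = brute_force_gls(
            tree, traits, cfg.response_name, cfg.predictor_name, fit.lam)
        assert fit.slope == pytest.approx(slope_bf, abs=1e-8)
        assert fit.intercept == pytest.approx(int_bf, abs=1e-8)

    def test_residual_df_and_r2_invariants(self, fitted20):
        assert fitted20.residual_df == fitted20.n - 2
        assert 0.0 <= fitted20.r_squared <= 1.0

    def test_raw_scale_shift_moves_only_intercept(self, sim_dataset20):
        cfg, tree, traits = sim_dataset20
        fit = fit_pgls(tree, traits, cfg.response_name, cfg.predictor_name)
        scaled = TraitTable(traits.df * 10.0)
        fit10 = fit_pgls(tree, scaled, cfg.response_name, cfg.predictor_name)
        assert fit10.slope == pytest.approx(fit.slope, abs=1e-8)
        assert fit10.lam == pytest.approx(fit.lam, abs=1e-4)
        assert fit10.r_squared == pytest.approx(fit.r_squared, abs=1e-6)
        # y*10, x*10 on log10 scale: intercept shifts by 1 - slope
        assert fit10.intercept == pytest.approx(
            fit.intercept + 1.0 - fit.slope, abs=1e-6)

    def test_pgls_lambda1_equals_contrasts_through_origin(self):
        # classic identity on binary ultrametric trees
        for seed in range(5):
            cfg = SimulationConfig(seed=seed + 60, n_tips=20)
            tree = simulate_tree(cfg)
            traits = simulate_allometric_traits(tree, cfg)
            fit = fit_pgls(tree, traits, cfg.response_name,
                           cfg.predictor_name, lam=1.0)
            ux, uy = [], []
            node_x = {}
            node_v = {}
            vals = {
                "x": {s: np.log10(traits.df.loc[s, cfg.predictor_name])
                      for s in traits.species},
                "y": {s: np.log10(traits.df.loc[s, cfg.response_name])
                      for s in traits.species}}
            for key, out in (("x", ux), ("y", uy)):
                node_x.clear(); node_v.clear()
                for node in tree.dendropy_tree.postorder_node_iter():
                    if node.is_leaf():
                        node_x[node] = vals[key][node.taxon.label]
                        node_v[node] = node.edge.length
                    else:
                        a, b = node.child_nodes()
                        va, vb = node_v[a], node_v[b]
                        out.append((node_x[a] - node_x[b]) / np.sqrt(va + vb))
                        node_x[node] = ((node_x[a] / va + node_x[b] / vb)
                                        / (1 / va + 1 / vb))
                        node_v[node] = ((node.edge.length or 0.0)
                                        + va * vb / (va + vb))
            ux, uy = np.array(ux), np.array(uy)
            slope_pic = float(ux @ uy / (ux @ ux))
            assert fit.slope == pytest.approx(slope_pic, abs=1e-6)


class TestValidation:
    def test_non_positive_trait_names_species(self, sim_dataset20):
        cfg, tree, traits = sim_dataset20
        df = traits.df.copy()
        df.loc["sp003", cfg.response_name] = -1.0
        with pytest.raises(ValidationError, match="sp003"):
            fit_pgls(tree, TraitTable(df.reset_index()), cfg.response_name,
                     cfg.predictor_name)

    def test_species_mismatch_is_hard_error_unless_intersect(
            self, sim_dataset20):
        cfg, tree, traits = sim_dataset20
        df = traits.df.iloc[:-2].reset_index()
        with pytest.raises(ValidationError, match="symmetric"):
            fit_pgls(tree, TraitTable(df), cfg.response_name,
                     cfg.predictor_name)
        fit = fit_pgls(tree, TraitTable(df), cfg.response_name,
                       cfg.predictor_name, intersect=True)
        assert fit.n == len(df)

    def test_too_few_species_rejected(self, three_tip_tree):
        traits = TraitTable(pd.DataFrame(
            {"species": ["A", "B", "C"], "p": [1, 2, 3], "r": [1, 2, 3]}))
        with pytest.raises(ValidationError, match="at least 4"):
            fit_pgls(three_tip_tree, traits, "r", "p")

    def test_singular_covariance_names_lambda(self):
        # zero-length cherry gives two identical covariance rows at λ=1
        tree2 = PhyloTree.from_newick("((A:0,B:0):1,(C:1,D:1,E:1,F:1):1);")
        traits = TraitTable(pd.DataFrame(
            {"species": list("ABCDEF"), "p": [1, 2, 3, 4, 5, 6],
             "r": [2, 3, 4, 5, 6, 7]}))
        with pytest.raises(NumericalError, match="lambda=1"):
            fit_pgls(tree2, traits, "r", "p", lam=1.0)


class TestProfileLambda:
    def test_empty_grid_rejected(self, sim_dataset20):
        cfg, tree, traits = sim_dataset20
        with pytest.raises(ValidationError):
            profile_lambda(tree, traits, cfg.response_name,
                           cfg.predictor_name, [])

    def test_ml_lambda_maximizes_profile(self, sim_dataset20, fitted20):
        cfg, tree, traits = sim_dataset20
        grid = np.linspace(0, 1, 21)
        prof = profile_lambda(tree, traits, cfg.response_name,
                              cfg.predictor_name, grid)
        assert fitted20.loglik >= prof["loglik"].max() - 1e-6
        best = prof.loc[prof["loglik"].idxmax(), "lambda"]
        assert abs(best - fitted20.lam) <= 0.05 + 1e-9

    def test_strong_signal_data_maximize_near_one(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed + 200, n_tips=128, lam=1.0,
                                   sigma2=0.05)
            tree = simulate_tree(cfg)
            traits = simulate_allometric_traits(tree, cfg)
            prof = profile_lambda(tree, traits, cfg.response_name,
                                  cfg.predictor_name, np.linspace(0, 1, 11))
            best = prof.loc[prof["loglik"].idxmax(), "lambda"]
            hits += best >= 0.9
        assert hits >= 6  # majority at or adjacent to 1

    def test_shuffled_tips_destroy_signal(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed + 300, n_tips=128, lam=1.0,
                                   sigma2=0.05)
            tree = simulate_tree(cfg)
            traits = simulate_allometric_traits(tree, cfg)
            rng = np.random.default_rng(seed)
            df = traits.df.copy()
            df.index = pd.Index(rng.permutation(df.index.to_numpy()),
                                name="species")
            prof = profile_lambda(tree, TraitTable(df.reset_index()),
                                  cfg.response_name, cfg.predictor_name,
                                  np.linspace(0, 1, 11))
            best = prof.loc[prof["loglik"].idxmax(), "lambda"]
            hits += best <= 0.3
        assert hits >= 6


class TestAllometryTable:
    def test_rows_match_individual_fits(self, sim_dataset20):
        cfg, tree, traits = sim_dataset20
        df = traits.df.copy()
        rng = np.random.default_rng(1)
        df["third"] = df[cfg.predictor_name] * 10 ** rng.normal(0, 0.1, len(df))
        tt = TraitTable(df.reset_index())
        pairs = [(cfg.response_name, cfg.predictor_name),
                 ("third", cfg.predictor_name)]
        table = allometry_table(tree, tt, pairs)
        assert len(table) == 2
        for _, row in table.iterrows():
            fit = fit_pgls(tree, tt, row["response"], row["predictor"])
            assert row["slope"] == pytest.approx(fit.slope, abs=1e-10)

    def test_empty_pairs_gives_empty_table(self, sim_dataset20):
        _, tree, traits = sim_dataset20
        assert len(allometry_table(tree, traits, [])) == 0

    def test_minus_adjustment_applied_on_raw_scale(self, sim_dataset20):
        cfg, tree, traits = sim_dataset20
        table = allometry_table(
            tree, traits,
            [(cfg.response_name, cfg.predictor_name, cfg.response_name)])
        name = f"{cfg.predictor_name}_minus_{cfg.response_name}"
        assert table.loc[0, "predictor"] == name
        derived = traits.with_difference(cfg.predictor_name,
                                         cfg.response_name, name)
        fit = fit_pgls(tree, derived, cfg.response_name, name)
        assert table.loc[0, "slope"] == pytest.approx(fit.slope, abs=1e-10)

    def test_errors_propagate_per_row_without_stopping(self, sim_dataset20):
        cfg, tree, traits = sim_dataset20
        table = allometry_table(
            tree, traits, [("missing_trait", cfg.predictor_name),
                           (cfg.response_name, cfg.predictor_name)])
        assert table.loc[0, "error"] != ""
        assert table.loc[1, "error"] == ""
        assert np.isfinite(table.loc[1, "slope"])
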