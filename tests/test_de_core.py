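"""DE core: normalization, dispersion engines, exact test, BH, run_de."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson

from polypde.de_core import (
    DispersionFit,
    bh_adjust,
    estimate_dispersion,
    nb_exact_test,
    run_de,
    significant,
    size_factors,
)
from polypde.gametic_adjustment import pooled_conditions, split_sex_conditions
from polypde.synthetic_data import SimulationParams, default_design, simulate_counts


def enumeration_oracle(k_a, k_b, s_a, s_b, alpha):
    """Independent split enumeration using scipy's NB/Poisson pmfs."""
    ka, kb = int(sum(k_a)), int(sum(k_b))
    total = ka + kb
    sa, sb = float(sum(s_a)), float(sum(s_b))
    q = total / (sa + sb)
    mu_a, mu_b = q * sa, q * sb
    aa = alpha * sum(s**2 for s in s_a) / sa**2
    ab = alpha * sum(s**2 for s in s_b) / sb**2

    def lp(x, mu, a):
        if a <= 0:
            return poisson.logpmf(x, mu)
        r = 1.0 / a
        return nbinom.logpmf(x, r, r / (r + mu))

    grid = np.arange(total + 1)
    lf = lp(grid, mu_a, aa) + lp(total - grid, mu_b, ab)
    l_obs = lf[ka]
    return float(np.exp(logsumexp(lf[lf <= l_obs + 1e-10]) - logsumexp(lf)))


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        col = pd.Series([3, 10, 50, 7])
        counts = pd.DataFrame({"L1": col, "L2": col, "L3": col})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_gives_sqrt2_split(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 100, size=20)
        counts = pd.DataFrame({"L1": base, "L2": 2 * base})
        s = size_factors(counts)
        assert s["L1"] == pytest.approx(1 / np.sqrt(2))
        assert s["L2"] == pytest.approx(np.sqrt(2))

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = rng.integers(1, 500, size=(5, 4)).astype(float)
            counts = pd.DataFrame(k, columns=list("ABCD"))
            s = size_factors(counts)
            geo = np.exp(np.log(k).mean(axis=1))
            expected = [float(np.median(k[:, j] / geo)) for j in range(4)]
            assert np.allclose(s.to_numpy(), expected)

    def test_error_without_all_positive_row(self):
        counts = pd.DataFrame({"L1": [0, 5], "L2": [3, 0]})
        with pytest.raises(ValueError, match="positive"):
            size_factors(counts)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            ours = bh_adjust(p)
            m = len(p)
            order = np.argsort(p)
            oracle = np.empty(m)
            for rank_pos, idx in enumerate(order):
                candidates = [
                    p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
                ]
                oracle[idx] = min(1.0, min(candidates))
            assert np.allclose(ours, oracle)

    def test_not_tested_entries_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.02])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], bh_adjust([0.01, 0.02]))

    def test_padj_never_below_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-4, 1, size=100)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestNbExactTest:
    def test_symmetric_split_has_p_one(self):
        for k in (1, 3, 10):
            assert nb_exact_test([k], [k], [1.0], [1.0], 0.0) == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        p1 = nb_exact_test([10, 2], [0, 1], [1, 1.2], [0.9, 1], 0.1)
        p2 = nb_exact_test([0, 1], [10, 2], [0.9, 1], [1, 1.2], 0.1)
        assert p1 == pytest.approx(p2)

    def test_extreme_split_matches_enumeration(self):
        p = nb_exact_test([10], [0], [1.0], [1.0], 0.1)
        assert p == pytest.approx(enumeration_oracle([10], [0], [1.0], [1.0], 0.1))

    def test_zero_total_is_not_tested(self):
        assert np.isnan(nb_exact_test([0, 0], [0], [1, 1], [1], 0.2))

    def test_matches_enumeration_oracle_randomized(self):
        rng = np.random.default_rng(4)
        worst = 0.0
        for _ in range(200):
            total = int(rng.integers(1, 201))
            ka = int(rng.integers(0, total + 1))
            s_a = rng.uniform(0.5, 2.0, size=int(rng.integers(1, 5)))
            s_b = rng.uniform(0.5, 2.0, size=int(rng.integers(1, 5)))
            alpha = float(rng.choice([0.0, 0.01, 0.1, 0.5, 2.0]))
            p = nb_exact_test([ka], [total - ka], s_a, s_b, alpha)
            worst = max(worst, abs(p - enumeration_oracle([ka], [total - ka], s_a, s_b, alpha)))
        assert worst < 1e-9

    def test_grid_path_close_to_exact(self):
        s_a, s_b = [1.1, 0.7], [1.4, 0.9]
        k_a, k_b = [9000.0, 5500.0], [3000.0, 2100.0]
        exact = nb_exact_test(k_a, k_b, s_a, s_b, 0.08, cap=50_000)
        grid = nb_exact_test(k_a, k_b, s_a, s_b, 0.08, cap=5_000)
        assert grid == pytest.approx(exact, rel=0.02)

    def test_rejects_invalid_dispersion(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [1], [1], [1], -0.5)


class TestEstimateDispersion:
    def test_poisson_data_has_near_zero_raw_dispersion(self, design):
        params = SimulationParams(
            n_transcripts=5000, seed=6, class_proportions={"null": 1.0},
            dispersion_log_mean=None,
        )
        counts, _ = simulate_counts(params, design)
        fit = estimate_dispersion(
            counts, size_factors(counts), pooled_conditions(design), "conservative"
        )
        assert np.nanmean(fit.table["raw_alpha"]) <= 0.01

    @pytest.mark.parametrize("engine", ["conservative", "shrinkage"])
    def test_recovers_constant_dispersion(self, design, engine):
        params = SimulationParams(
            n_transcripts=5000, seed=7, class_proportions={"null": 1.0},
            dispersion_log_mean=np.log(0.2), dispersion_log_sd=0.0,
        )
        counts, truth = simulate_counts(params, design)
        assert np.allclose(truth["true_dispersion"], 0.2)
        fit = estimate_dispersion(
            counts, size_factors(counts), pooled_conditions(design), engine
        )
        assert 0.1 <= np.nanmedian(fit.table["final_alpha"]) <= 0.4

    def test_conservative_final_is_max_of_raw_and_fitted(self, design, small_sim):
        _, counts, _ = small_sim
        fit = estimate_dispersion(
            counts, size_factors(counts), pooled_conditions(design), "conservative"
        )
        t = fit.table.dropna()
        assert np.allclose(t["final_alpha"], np.maximum(t["raw_alpha"], t["fitted_alpha"]))

    @pytest.mark.parametrize("engine", ["conservative", "shrinkage"])
    def test_sex_split_grouping_lowers_dispersion(self, design, engine):
        # strong heterogametic effects inflate pooled-gonozooid dispersion
        params = SimulationParams(n_transcripts=2000, seed=8)
        counts, _ = simulate_counts(params, design)
        s = size_factors(counts)
        pooled = estimate_dispersion(counts, s, pooled_conditions(design), engine)
        split = estimate_dispersion(counts, s, split_sex_conditions(design), engine)
        assert (
            np.nanmean(split.table["final_alpha"])
            < np.nanmean(pooled.table["final_alpha"])
        )

    def test_single_library_conditions_rejected(self, design, small_sim):
        _, counts, _ = small_sim
        singletons = {lib: lib for lib in counts.columns}
        with pytest.raises(ValueError, match=">= 2"):
            estimate_dispersion(counts, size_factors(counts), singletons, "conservative")


class TestRunDe:
    def test_identical_groups_are_null(self, design):
        rng = np.random.default_rng(9)
        base = rng.poisson(50, size=(400, 4))
        counts = pd.DataFrame(
            np.hstack([base, base]),
            columns=["Ga1", "Ga2", "Ga3", "Ga4", "Da1", "Da2", "Da3", "Da4"],
            index=[f"t{i}" for i in range(400)],
        )
        # dactylozooid columns are copies of the gastrozooid columns
        sub_design = design[design["library_id"].isin(counts.columns)]
        de = run_de(
            counts, sub_design, ("gastrozooid", "dactylozooid"), "conservative",
            group_a=["Ga1", "Ga2", "Ga3", "Ga4"], group_b=["Da1", "Da2", "Da3", "Da4"],
        )
        assert np.allclose(de["log2_fold_change"][de["tested"]], 0.0, atol=1e-12)
        assert int(significant(de).sum()) == 0

    def test_null_simulation_no_bh_significance(self, design):
        params = SimulationParams(
            n_transcripts=1000, seed=10, class_proportions={"null": 1.0}
        )
        counts, _ = simulate_counts(params, design)
        for engine in ("conservative", "shrinkage"):
            de = run_de(counts, design, ("dactylozooid", "gastrozooid"), engine)
            assert int(significant(de).sum()) == 0

    def test_planted_effect_direction_recovered(self, design):
        params = SimulationParams(
            n_transcripts=1200, seed=11, log2_effect=2.0,
            class_proportions={"null": 0.5, "dact_up": 0.25, "dact_down": 0.25},
            baseline_log2_range=(7.0, 12.0),
        )
        counts, truth = simulate_counts(params, design)
        de = run_de(counts, design, ("dactylozooid", "gastrozooid"), "shrinkage")
        sig = significant(de)
        affected = truth.index[truth["effect_class"] != "null"]
        detected = [t for t in affected if sig[t]]
        assert len(detected) / len(affected) > 0.9
        signs = np.sign(de.loc[detected, "log2_fold_change"])
        expected = truth.loc[detected, "effect_class"].map(
            {"dact_up": 1.0, "dact_down": -1.0}
        )
        assert (signs == expected).mean() >= 0.99

    def test_all_zero_transcripts_not_tested_and_excluded_from_m(self, design, small_sim):
        _, counts, _ = small_sim
        counts = counts.copy()
        counts.iloc[:5] = 0
        de = run_de(counts, design, ("gastrozooid", "gonozooid"), "conservative")
        head = de.iloc[:5]
        assert (~head["tested"]).all()
        assert head["p_value"].isna().all() and head["p_adj"].isna().all()
        # BH m equals the tested count
        tested_p = de.loc[de["tested"], "p_value"].to_numpy()
        assert np.allclose(
            de.loc[de["tested"], "p_adj"].to_numpy(), bh_adjust(tested_p)
        )

    def test_padj_at_least_p(self, design, small_sim):
        _, counts, _ = small_sim
        de = run_de(counts, design, ("dactylozooid", "gonozooid"), "conservative")
        t = de[de["tested"]]
        assert (t["p_adj"] >= t["p_value"] - 1e-12).all()

    def test_engine_mismatch_with_precomputed_fit_rejected(self, design, small_sim):
        _, counts, _ = small_sim
        fit = estimate_dispersion(
            counts, size_factors(counts), pooled_conditions(design), "conservative"
        )
        with pytest.raises(ValueError, match="engine"):
            run_de(counts, design, ("gastrozooid", "gonozooid"), "shrinkage", dispersion=fit)

    def test_unknown_condition_rejected(self, design, small_sim):
        _, counts, _ = small_sim
        with pytest.raises(ValueError, match="unknown condition"):
            run_de(counts, design, ("gastrozooid", "tentaculozooid"), "conservative")
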