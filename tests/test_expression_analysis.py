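"""TMM, FPKM, NB differential expression, BH, ddCt, and clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mybkit.expression_analysis import (
    CoexpressionClustering,
    TmmConfig,
    benjamini_hochberg,
    coexpression_clusters,
    compute_fpkm,
    delta_delta_ct,
    differential_expression,
    tmm_factors,
)
from mybkit.synthetic_data import DePlanting, SimulationConfig, simulate_counts


def _counts(seed=0, n_genes=400, fraction_de=0.0, dispersion=0.1, lfc=2.0):
    cfg = SimulationConfig(seed=seed, n_expression_genes=n_genes,
                           de_plantings=DePlanting(fraction_de, lfc, dispersion))
    return simulate_counts(cfg)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.random.default_rng(0).integers(1, 500, size=200)
        counts = pd.DataFrame({"s1": col, "s2": col, "s3": col})
        assert tmm_factors(counts) == pytest.approx(np.ones(3))

    def test_pure_depth_scaling_is_compensated(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 1000, size=300)
        counts = pd.DataFrame({"s1": base, "s2": 2 * base})
        factors = tmm_factors(counts)
        lib = counts.sum(axis=0).to_numpy()
        normalized = counts.to_numpy() / (lib * factors)
        assert normalized[:, 0] == pytest.approx(normalized[:, 1], rel=1e-6)

    def test_scaling_one_library_leaves_normalized_means_invariant(self):
        counts, _ = _counts(seed=3, n_genes=500)
        counts = counts["EG"]
        f0 = tmm_factors(counts)
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 4
        f1 = tmm_factors(scaled)
        m0 = counts.to_numpy() / (counts.sum(0).to_numpy() * f0)
        m1 = scaled.to_numpy() / (scaled.sum(0).to_numpy() * f1)
        assert m1.mean(axis=0) == pytest.approx(m0.mean(axis=0), rel=1e-6)

    def test_asymmetric_inflation_is_trimmed_away(self):
        # 5% of genes 8-fold up in one sample: trimming removes them, so the
        # effective library (raw size x factor) matches the clean sample's
        rng = np.random.default_rng(2)
        base = rng.integers(50, 500, size=1000).astype(float)
        clean = pd.DataFrame({"s1": base, "s2": base})
        inflated = clean.copy()
        idx = rng.choice(1000, size=50, replace=False)
        inflated.iloc[idx, 1] *= 8
        eff_clean = clean.sum(0).to_numpy() * tmm_factors(clean)
        eff_infl = inflated.sum(0).to_numpy() * tmm_factors(inflated)
        assert eff_infl[1] / eff_infl[0] == pytest.approx(
            eff_clean[1] / eff_clean[0], rel=0.02
        )

    def test_all_zero_sample_is_degenerate(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(counts)

    def test_invalid_trim_rejected(self):
        with pytest.raises(ValueError):
            TmmConfig(logratio_trim=0.6)


class TestFpkm:
    def test_textbook_value(self):
        counts = pd.DataFrame({"s": [100, 0]})
        counts.loc[2] = 0  # pad library
        counts.iloc[1, 0] = 10_000_000 - 100
        fpkm = compute_fpkm(counts, [1000, 1000, 1000], np.ones(1))
        assert fpkm.iloc[0, 0] == pytest.approx(10.0)
        assert fpkm.iloc[2, 0] == 0.0

    def test_doubling_length_halves_fpkm(self):
        counts = pd.DataFrame({"s1": [100, 100], "s2": [50, 80]})
        f1 = compute_fpkm(counts, [500, 500])
        f2 = compute_fpkm(counts, [500, 1000])
        assert f2.iloc[1, 0] == pytest.approx(f1.iloc[1, 0] / 2)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            compute_fpkm(pd.DataFrame({"s": [1]}), [0])


class TestBenjaminiHochberg:
    def test_matches_direct_step_up_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(3, 50))
            adj = benjamini_hochberg(p)
            n = len(p)
            order = np.argsort(p)
            direct = np.empty(n)
            running = 1.0
            for rank in range(n - 1, -1, -1):
                i = order[rank]
                running = min(running, p[i] * n / (rank + 1))
                direct[i] = running
            assert adj == pytest.approx(direct)

    def test_monotone_in_p_rank(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        adj = benjamini_hochberg(p)
        assert list(adj) == sorted(adj)


class TestDifferentialExpression:
    def test_identical_groups_yield_no_significant_genes(self):
        rng = np.random.default_rng(5)
        block = rng.poisson(100, size=(300, 2))
        counts = pd.DataFrame(np.hstack([block, block]),
                              columns=["a1", "a2", "b1", "b2"])
        res = differential_expression(counts, ["A", "A", "B", "B"])
        assert not res.significant.any()

    def test_null_simulation_controls_false_positives(self):
        fracs = []
        for seed in range(5):
            counts, _ = _counts(seed=seed, n_genes=1000, fraction_de=0.0)
            sub = counts.loc[:, ["EG", "MG"]]
            res = differential_expression(sub, [c[0] for c in sub.columns])
            fracs.append((res.adj_p < 0.01).mean())
        assert np.mean(fracs) <= 0.01

    def test_planted_fold_changes_are_recovered(self):
        counts, truth = _counts(seed=7, n_genes=1000, fraction_de=0.1)
        sub = counts.loc[:, ["EG", "MG"]]
        res = differential_expression(sub, [c[0] for c in sub.columns],
                                      tmm_factors(sub))
        de = truth.true_log2fc != 0
        recall = (res.significant.to_numpy() & de.to_numpy()).sum() / de.sum()
        assert recall >= 0.8

    def test_significance_is_exactly_the_stated_conjunction(self):
        counts, _ = _counts(seed=8, n_genes=500, fraction_de=0.2)
        sub = counts.loc[:, ["EG", "MG"]]
        res = differential_expression(sub, [c[0] for c in sub.columns])
        expected = (res.adj_p < 0.01) & (res.log2fc.abs() > np.log2(1.5))
        assert (res.significant == expected).all()

    def test_single_replicate_group_is_a_design_error(self):
        counts = pd.DataFrame({"a1": [1], "a2": [2], "b1": [3]})
        with pytest.raises(ValueError):
            differential_expression(counts, ["A", "A", "B"])


class TestDeltaDeltaCt:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "condition", "ct_target",
                                           "ct_reference"])

    def test_zero_ddct_is_unit_expression(self):
        df = self._frame([("g", "cal", 20.0, 15.0), ("g", "cond", 20.0, 15.0)])
        res = delta_delta_ct(df, "cal")
        assert res.loc[res.condition == "cond", "relative_expression"].item() == 1.0

    def test_one_cycle_doubles(self):
        df = self._frame([("g", "cal", 20.0, 15.0), ("g", "cond", 19.0, 15.0)])
        res = delta_delta_ct(df, "cal")
        assert res.loc[res.condition == "cond", "relative_expression"].item() == 2.0

    def test_worked_example(self):
        df = self._frame([("g", "cal", 22.0, 15.0), ("g", "treat", 20.0, 15.0)])
        res = delta_delta_ct(df, "cal").set_index("condition")
        assert res.loc["treat", "ddct"] == -2.0
        assert res.loc["treat", "relative_expression"] == 4.0

    def test_calibrator_expression_is_one(self):
        df = self._frame([("g", "cal", 21.0, 15.0), ("g", "x", 19.0, 15.0)])
        res = delta_delta_ct(df, "cal").set_index("condition")
        assert res.loc["cal", "relative_expression"] == 1.0

    def test_global_ct_shift_is_invariant(self):
        rows = [("g", "cal", 22.0, 15.0), ("g", "cal", 22.4, 15.2),
                ("g", "t", 20.1, 15.1), ("g", "t", 19.9, 14.9)]
        df = self._frame(rows)
        shifted = df.assign(ct_target=df.ct_target + 3, ct_reference=df.ct_reference + 3)
        r1 = delta_delta_ct(df, "cal")
        r2 = delta_delta_ct(shifted, "cal")
        assert r1.relative_expression.to_numpy() == pytest.approx(
            r2.relative_expression.to_numpy()
        )

    def test_replicates_get_a_t_test(self):
        rows = [("g", "cal", 22.0, 15.0), ("g", "cal", 22.2, 15.1),
                ("g", "cal", 21.9, 15.0),
                ("g", "t", 19.0, 15.0), ("g", "t", 19.2, 15.1), ("g", "t", 18.9, 15.0)]
        res = delta_delta_ct(self._frame(rows), "cal").set_index("condition")
        assert res.loc["t", "p"] < 0.05

    def test_missing_calibrator_is_an_error(self):
        df = self._frame([("g", "x", 20.0, 15.0)])
        with pytest.raises(ValueError):
            delta_delta_ct(df, "cal")


class TestCoexpression:
    def test_identical_profiles_share_a_cluster(self):
        prof = [1.0, 5.0, 2.0, 8.0]
        fpkm = pd.DataFrame([prof, prof, [9, 1, 7, 0]], index=["g1", "g2", "g3"])
        clus = coexpression_clusters(fpkm, k=2)
        assert clus.assignments["g1"] == clus.assignments["g2"]
        assert clus.assignments["g1"] != clus.assignments["g3"]

    def test_anticorrelated_groups_separate_at_k2(self):
        up = [1.0, 2.0, 4.0, 8.0]
        down = [8.0, 4.0, 2.0, 1.0]
        fpkm = pd.DataFrame([up, up, down, down], index=list("abcd"))
        clus = coexpression_clusters(fpkm, k=2)
        a = clus.assignments
        assert a["a"] == a["b"] and a["c"] == a["d"] and a["a"] != a["c"]

    def test_constant_profiles_get_the_dedicated_cluster(self):
        fpkm = pd.DataFrame([[3.0, 3.0, 3.0], [1.0, 5.0, 9.0], [9.0, 5.0, 1.0]],
                            index=list("abc"))
        clus = coexpression_clusters(fpkm, k=2)
        assert clus.assignments["a"] == 0
        assert set(clus.assignments[["b", "c"]]) == {1, 2}

    def test_archetype_recovery_with_noise(self):
        rng = np.random.default_rng(10)
        archetypes = np.array([[0, 2, 4, 6, 8, 10], [10, 8, 6, 4, 2, 0],
                               [0, 10, 0, 10, 0, 10]], dtype=float)
        scores = []
        for _ in range(10):
            truth, rows = [], []
            for g in range(60):
                k = g % 3
                truth.append(k)
                rows.append(2 ** (archetypes[k] + rng.normal(0, 0.2, 6)) - 1)
            fpkm = pd.DataFrame(rows)
            clus = coexpression_clusters(fpkm, k=3)
            scores.append(adjusted_rand_score(truth, clus.assignments.to_numpy()))
        assert np.mean(scores) >= 0.9

    def test_more_clusters_than_genes_rejected(self):
        fpkm = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            coexpression_clusters(fpkm, k=5)

    def test_exactly_one_of_k_or_height(self):
        fpkm = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            coexpression_clusters(fpkm)
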