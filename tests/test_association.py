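"""Distance statistics, hypothesis tests, class recovery, elastic nets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from rxvar import association as assoc


def mk_matrix(rng, n=20, d=8, index=None):
    return pd.DataFrame(
        rng.standard_normal((n, d)),
        index=index or [f"c{i:03d}" for i in range(n)],
        columns=[f"D{j}" for j in range(d)],
    )


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        rng = np.random.default_rng(1)
        M = mk_matrix(rng)
        M.iloc[1] = M.iloc[0]
        out = assoc.pairwise_distances(M, "deviance")
        pair = out[(out["county_a"] == "c000") & (out["county_b"] == "c001")]
        assert pair["dist_deviance"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_geographic_distance_is_planar_euclidean(self):
        M = pd.DataFrame(
            {"lat": [0.0, 3.0], "lon": [0.0, 4.0]}, index=["a", "b"]
        )
        out = assoc.pairwise_distances(M, "geographic")
        assert out["dist_geographic"].iloc[0] == pytest.approx(5.0)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(2)
        M = mk_matrix(rng, n=10)
        out = assoc.pairwise_distances(M, "deviance")
        d = {frozenset((a, b)): v for a, b, v in
             zip(out["county_a"], out["county_b"], out["dist_deviance"])}
        ids = list(M.index)
        for _ in range(50):
            a, b, c = rng.choice(ids, 3, replace=False)
            assert d[frozenset((a, b))] <= d[frozenset((a, c))] + d[frozenset((b, c))] + 1e-9

    def test_pair_count_and_determinism(self):
        rng = np.random.default_rng(3)
        M = mk_matrix(rng, n=12)
        o1 = assoc.pairwise_distances(M, "deviance")
        o2 = assoc.pairwise_distances(M, "deviance")
        assert len(o1) == 12 * 11 // 2
        pd.testing.assert_frame_equal(o1, o2)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = assoc.spearman_test([1, 2, 3, 4, 5, 6], [2, 4, 9, 16, 30, 60])
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_exactly_zero_correlation_gives_p_one(self):
        rho, p = assoc.spearman_test([1, 2, 3, 4], [2, 4, 1, 3])
        assert rho == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            assoc.spearman_test([1, 1, 1], [1, 2, 3])


class TestBorderRegression:
    def mk_pairs(self, rng, n=300, beta_ss=-1.2, sigma=0.5):
        demo = rng.uniform(0, 3, n)
        ss = rng.random(n) < 0.4
        y = 1.0 + 0.5 * demo + beta_ss * ss + sigma * rng.standard_normal(n)
        # counties repeat across pairs so same-state pairs share border counties
        return pd.DataFrame(
            {
                "county_a": [f"a{i % 25}" for i in range(n)],
                "county_b": [f"b{i}" for i in range(n)],
                "dist_deviance": y,
                "dist_demographic": demo,
                "same_state": ss,
                "is_border": True,
            }
        )

    def test_planted_effect_recovered_within_three_se(self):
        rng = np.random.default_rng(4)
        res = assoc.border_samestate_regression(self.mk_pairs(rng))
        assert abs(res["coef"]["same_state"] - (-1.2)) < 3 * res["se"]["same_state"]
        assert res["same_state_F_p"] < 1e-6

    def test_constant_demographic_distance_dropped(self):
        rng = np.random.default_rng(5)
        pairs = self.mk_pairs(rng)
        pairs["dist_demographic"] = 1.0
        res = assoc.border_samestate_regression(pairs)
        assert "dist_demographic" in res["dropped"]
        assert "same_state" in res["coef"]

    def test_no_cross_state_pairs_rejected(self):
        rng = np.random.default_rng(6)
        pairs = self.mk_pairs(rng)
        pairs["same_state"] = True
        with pytest.raises(ValueError):
            assoc.border_samestate_regression(pairs)


class TestClassRecovery:
    def test_greedy_collapse_merges_highest_overlap(self):
        cm = {"d1": ["A", "B"], "d2": ["A", "B"], "d3": ["B"], "d4": ["C"]}
        out = assoc.collapse_classes(cm, 2)
        labels = {c for cls in out.values() for c in cls}
        assert len(labels) == 2
        assert any("A" in l and "B" in l for l in labels)  # A,B merged (Jaccard 2/3)

    def test_block_structure_gives_high_ari(self):
        rng = np.random.default_rng(7)
        n, per = 40, 5
        profiles = rng.standard_normal((3, n)) * 3
        cols, cmap = {}, {}
        for k in range(3):
            for j in range(per):
                name = f"D{k}{j}"
                cols[name] = profiles[k] + 0.1 * rng.standard_normal(n)
                cmap[name] = [f"CL{k}"]
        M = pd.DataFrame(cols)
        rep = assoc.class_recovery_rand(M, cmap, 3, n_assign=5, n_perm=20, seed=1)
        assert rep["observed_ari"].mean() > 0.95

    def test_random_labels_have_near_zero_expected_ari(self):
        rng = np.random.default_rng(8)
        M = mk_matrix(rng, n=30, d=24)
        cmap = {d: [f"CL{rng.integers(4)}"] for d in M.columns}
        rep = assoc.class_recovery_rand(M, cmap, 4, n_assign=50, n_perm=200, seed=2)
        assert abs(rep["null_ari"].mean()) < 0.05

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(9)
        M = mk_matrix(rng, n=20, d=10)
        cmap = {d: [f"CL{i % 3}"] for i, d in enumerate(M.columns)}
        r1 = assoc.class_recovery_rand(M, cmap, 3, 10, 20, seed=5)
        r2 = assoc.class_recovery_rand(M, cmap, 3, 10, 20, seed=5)
        np.testing.assert_array_equal(r1["observed_ari"], r2["observed_ari"])
        np.testing.assert_array_equal(r1["null_ari"], r2["null_ari"])

    def test_too_few_drugs_rejected(self):
        rng = np.random.default_rng(10)
        M = mk_matrix(rng, d=2)
        with pytest.raises(ValueError):
            assoc.class_recovery_rand(M, {"D0": ["A"], "D1": ["B"]}, 2, 1, 1)


class TestRankSum:
    def test_extreme_subset_attains_minimal_one_sided_p(self):
        vals = pd.Series([10.0, 9.0, 8.0, 1.0, 2.0, 3.0, 4.0, 5.0],
                         index=list("ABCDEFGH"))
        p = assoc.state_group_ranksum(vals, ["A", "B", "C"], alternative="greater")
        assert p == pytest.approx(1 / comb(8, 3), rel=1e-9)

    def test_single_state_subset(self):
        vals = pd.Series([5.0, 1.0, 2.0, 3.0], index=list("ABCD"))
        p = assoc.state_group_ranksum(vals, ["A"], alternative="greater")
        assert p == pytest.approx(0.25, rel=1e-9)

    def test_improper_subset_rejected(self):
        vals = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(ValueError):
            assoc.state_group_ranksum(vals, ["A", "B"])
        with pytest.raises(ValueError):
            assoc.state_group_ranksum(vals, ["Z"])


class TestElasticNet:
    def test_matching_predictor_dominates(self):
        rng = np.random.default_rng(11)
        X = mk_matrix(rng, n=80, d=10)
        y = pd.Series(X["D3"].to_numpy() + 0.05 * rng.standard_normal(80),
                      index=X.index)
        res = assoc.elastic_net_predict(y, X, seed=0)
        mass = res["coef"].abs()
        assert mass["D3"] / mass.sum() >= 0.9

    def test_noise_target_shrinks_to_zero(self):
        rng = np.random.default_rng(12)
        X = mk_matrix(rng, n=80, d=10)
        y = pd.Series(rng.standard_normal(80), index=X.index)
        res = assoc.elastic_net_predict(y, X, seed=0)
        assert res["r2"] < 0.15
        assert res["coef"].abs().max() < 0.3

    def test_multi_target_mode(self):
        rng = np.random.default_rng(13)
        X = mk_matrix(rng, n=60, d=8)
        Y = pd.DataFrame(
            {"t1": X["D0"] + 0.1 * rng.standard_normal(60),
             "t2": X["D0"] + 0.1 * rng.standard_normal(60)},
            index=X.index,
        )
        res = assoc.elastic_net_predict(Y, X, seed=0)
        assert res["coef"].shape == (8, 2)
        assert res["coef"].loc["D0"].abs().min() > 0.5

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(14)
        X = mk_matrix(rng, n=5)
        with pytest.raises(ValueError):
            assoc.elastic_net_predict(pd.Series(np.ones(5), index=X.index), X)


class TestDrugSetTest:
    def test_extreme_set_attains_minimal_p(self):
        coefs = pd.Series([5.0, 4.0, 0.1, 0.2, -0.1, 0.0, 0.05, -0.2],
                          index=[f"D{i}" for i in range(8)])
        p = assoc.drugset_coefficient_test(coefs, ["D0", "D1"])
        assert p == pytest.approx(2 / comb(8, 2), rel=1e-9)

    def test_empty_set_rejected(self):
        coefs = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(ValueError):
            assoc.drugset_coefficient_test(coefs, ["Z"])


class TestImputation:
    def mk_table(self, rng, n=40, d=5):
        tab = pd.DataFrame(
            rng.standard_normal((n, d)), columns=[f"demo_{j:02d}" for j in range(d)]
        )
        tab.insert(0, "county_id", [f"c{i:03d}" for i in range(n)])
        return tab

    def test_complete_table_unchanged(self):
        rng = np.random.default_rng(15)
        tab = self.mk_table(rng)
        out = assoc.impute_demographics(tab)
        pd.testing.assert_frame_equal(out, tab)

    def test_exact_linear_relation_imputed_exactly(self):
        rng = np.random.default_rng(16)
        tab = self.mk_table(rng)
        tab["demo_04"] = 2.0 * tab["demo_00"] - tab["demo_01"] + 0.5
        tab.loc[3, "demo_04"] = np.nan
        out = assoc.impute_demographics(tab)
        expect = 2.0 * tab.loc[3, "demo_00"] - tab.loc[3, "demo_01"] + 0.5
        assert out.loc[3, "demo_04"] == pytest.approx(expect, abs=1e-8)

    def test_mask_and_recover_beats_marginal_noise(self):
        rng = np.random.default_rng(17)
        n = 200
        base = rng.standard_normal(n)
        tab = pd.DataFrame({
            "county_id": [f"c{i}" for i in range(n)],
            "demo_00": base + 0.1 * rng.standard_normal(n),
            "demo_01": -base + 0.1 * rng.standard_normal(n),
            "demo_02": 2 * base + 0.2 * rng.standard_normal(n),
        })
        truth = tab["demo_02"].copy()
        mask = rng.choice(n, 8, replace=False)
        tab.loc[mask, "demo_02"] = np.nan
        out = assoc.impute_demographics(tab)
        rmse = np.sqrt(np.mean((out.loc[mask, "demo_02"] - truth[mask]) ** 2))
        assert rmse < truth.std()  # far better than marginal imputation

    def test_overly_missing_variable_dropped(self):
        rng = np.random.default_rng(18)
        tab = self.mk_table(rng)
        tab.loc[:20, "demo_03"] = np.nan
        out = assoc.impute_demographics(tab, max_missing=10)
        assert "demo_03" not in out.columns

    def test_all_missing_county_rejected(self):
        rng = np.random.default_rng(19)
        tab = self.mk_table(rng)
        tab.loc[0, [c for c in tab.columns if c.startswith("demo_")]] = np.nan
        with pytest.raises(ValueError, match="missing all"):
            assoc.impute_demographics(tab, max_missing=5)
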