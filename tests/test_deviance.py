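"""Weights, standardization, and the signed deviance residual."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxvar import deviance as dv


def mk(drug, bins, ns):
    return pd.DataFrame({"drug_id": drug, "bin_id": bins, "n": ns, "y": 0})


class TestWeights:
    def test_single_bin_gets_unit_weight(self):
        w = dv.compute_weights(mk("D", ["b1"], [42]))
        assert w["w"].iloc[0] == 1.0

    def test_proportional_split(self):
        w = dv.compute_weights(mk("D", ["b1", "b2"], [30, 70]))
        assert w.set_index("bin_id")["w"].to_dict() == {"b1": 0.3, "b2": 0.7}

    def test_scale_invariance(self):
        w1 = dv.compute_weights(mk("D", ["b1", "b2", "b3"], [10, 25, 65]))
        w2 = dv.compute_weights(mk("D", ["b1", "b2", "b3"], [30, 75, 195]))
        np.testing.assert_allclose(w1["w"], w2["w"])

    def test_weights_sum_to_one_per_drug(self):
        nc = pd.concat([mk("A", ["b1", "b2"], [5, 15]), mk("B", ["b1"], [9])])
        w = dv.compute_weights(nc)
        sums = w.groupby("drug_id")["w"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_empty_risk_set_drug_excluded(self):
        nc = pd.concat([mk("A", ["b1"], [10]), mk("B", ["b1"], [0])])
        w = dv.compute_weights(nc)
        assert set(w["drug_id"]) == {"A"}


class TestStandardize:
    def mk_inputs(self, p=(0.1, 0.1)):
        counts = pd.DataFrame(
            {
                "drug_id": "D",
                "bin_id": ["b1", "b2"],
                "county_id": "c1",
                "n": [10, 30],
                "y": [1, 3],
            }
        )
        weights = pd.DataFrame({"drug_id": "D", "bin_id": ["b1", "b2"], "w": [0.5, 0.5]})
        p_hat = pd.DataFrame({"drug_id": "D", "bin_id": ["b1", "b2"], "p": list(p)})
        return counts, weights, p_hat

    def test_weighted_sums_match_hand_computation(self):
        out = dv.standardize_and_expect(*self.mk_inputs())
        row = out.iloc[0]
        assert row["n_w"] == pytest.approx(20.0)
        assert row["y_w"] == pytest.approx(2.0)
        assert row["yhat_w"] == pytest.approx(2.0)

    def test_zero_probability_gives_zero_expectation(self):
        out = dv.standardize_and_expect(*self.mk_inputs(p=(0.0, 0.0)))
        assert out["yhat_w"].iloc[0] == 0.0

    def test_missing_probability_is_hard_error(self):
        counts, weights, p_hat = self.mk_inputs()
        with pytest.raises(ValueError, match="missing fitted probability"):
            dv.standardize_and_expect(counts, weights, p_hat.iloc[:1])


class TestResidual:
    def test_zero_departure_gives_zero(self):
        assert dv.deviance_residual(5.0, 5.0, 100.0) == 0.0

    def test_known_value(self):
        # high-precision evaluation of the un-doubled signed residual
        assert dv.deviance_residual(10.0, 5.0, 100.0) == pytest.approx(
            1.43715757357, abs=1e-9
        )

    def test_sign_convention(self):
        g_neg = dv.deviance_residual(5.0, 10.0, 100.0)
        assert g_neg < 0
        # magnitude is the square root of the bracket with y and yhat reversed
        assert abs(g_neg) == pytest.approx(
            np.sqrt(5 * np.log(5 / 10) + 95 * np.log(95 / 90)), abs=1e-10
        )

    def test_zero_observed_uses_xlogx_limit(self):
        g = dv.deviance_residual(0.0, 5.0, 100.0)
        expect = -np.sqrt(100 * np.log(100 / 95))
        assert g == pytest.approx(expect, abs=1e-10)

    def test_monotone_in_departure(self):
        n = 100.0
        gs = [dv.deviance_residual(y, 10.0, n) for y in (11, 15, 20, 30)]
        assert np.all(np.diff(np.abs(gs)) > 0)

    def test_boundary_expected_is_clamped_not_nan(self):
        g = dv.deviance_residual(np.array([3.0]), np.array([0.0]), np.array([10.0]))
        assert np.isfinite(g[0]) and g[0] > 0
        g2 = dv.deviance_residual(np.array([3.0]), np.array([10.0]), np.array([10.0]))
        assert np.isfinite(g2[0]) and g2[0] < 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            dv.deviance_residual(11.0, 5.0, 10.0)

    def test_null_binomial_calibration(self):
        # G ~ signed sqrt of an un-doubled deviance: mean ~ 0, SD ~ 1/sqrt(2)
        rng = np.random.default_rng(42)
        for n, p in ((200, 0.05), (1000, 0.1), (100, 0.3)):
            y = rng.binomial(n, p, 20000).astype(float)
            g = dv.deviance_residual(y, np.full(20000, n * p), np.full(20000, float(n)))
            assert abs(g.mean()) < 0.1
            assert 0.7 <= g.std() <= 1.5


class TestResidualProperties:
    @given(
        n=st.floats(1.0, 1e5),
        fy=st.floats(0.0, 1.0),
        fh=st.floats(0.001, 0.999),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_finite_signed_and_zero_at_equality(self, n, fy, fh):
        y, yhat = fy * n, fh * n
        g = dv.deviance_residual(y, yhat, n)
        assert np.isfinite(g)
        if abs(y - yhat) > 1e-6 * n:
            assert np.sign(g) == np.sign(y - yhat)
        assert dv.deviance_residual(yhat, yhat, n) == 0.0

    @given(
        ns=st.lists(st.integers(1, 10_000), min_size=1, max_size=8),
        scale=st.integers(2, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_weights_homogeneous_of_degree_zero(self, ns, scale):
        bins = [f"b{i}" for i in range(len(ns))]
        w1 = dv.compute_weights(mk("D", bins, ns))
        w2 = dv.compute_weights(mk("D", bins, [n * scale for n in ns]))
        np.testing.assert_allclose(w1["w"], w2["w"], rtol=1e-12)


class TestMatrix:
    def mk_summaries(self, rng, n_counties=30, n_drugs=5, n=200.0, p=0.04):
        rows = []
        for d in range(n_drugs):
            for c in range(n_counties):
                y = float(rng.binomial(int(n), p))
                rows.append(
                    {"drug_id": f"D{d}", "county_id": f"c{c:03d}",
                     "n_w": n, "y_w": y, "yhat_w": n * p}
                )
        return pd.DataFrame(rows)

    def test_null_column_means_near_zero(self):
        rng = np.random.default_rng(7)
        means = []
        for _ in range(20):
            G = dv.build_deviance_matrix(self.mk_summaries(rng))
            means.append(G.mean(axis=0))
        grand = pd.concat(means, axis=1).mean(axis=1)
        assert np.all(np.abs(grand) < 0.1)

    def test_low_person_year_counties_excluded(self):
        rng = np.random.default_rng(8)
        s = self.mk_summaries(rng, n_counties=10)
        s.loc[s["county_id"] == "c000", "n_w"] = 0.1
        G = dv.build_deviance_matrix(s, min_person_years=5.0)
        assert "c000" not in G.index

    def test_csv_round_trip_is_exact(self, tmp_path):
        rng = np.random.default_rng(9)
        G = dv.build_deviance_matrix(self.mk_summaries(rng))
        path = tmp_path / "deviance.csv"
        dv.write_deviance_csv(G, path)
        back = dv.read_deviance_csv(path)
        pd.testing.assert_frame_equal(G, back, check_exact=True, check_names=False)

    def test_sign_matches_departure(self):
        rng = np.random.default_rng(10)
        s = self.mk_summaries(rng)
        G = dv.build_deviance_matrix(s)
        for _, r in s.sample(20, random_state=1).iterrows():
            g = G.loc[r["county_id"], r["drug_id"]]
            if r["y_w"] != r["yhat_w"]:
                assert np.sign(g) == np.sign(r["y_w"] - r["yhat_w"])

    def test_state_aggregation_preserves_totals(self):
        rng = np.random.default_rng(12)
        s = self.mk_summaries(rng, n_counties=12)
        mapping = pd.Series(
            {f"c{c:03d}": f"S{c % 3}" for c in range(12)}
        )
        agg = dv.aggregate_summaries(s, mapping)
        assert set(agg["county_id"]) == {"S0", "S1", "S2"}
        np.testing.assert_allclose(
            agg.groupby("drug_id")["y_w"].sum().to_numpy(),
            s.groupby("drug_id")["y_w"].sum().to_numpy(),
        )
        G = dv.build_deviance_matrix(agg)
        assert G.shape == (3, 5)

    def test_log_ratio_companion_shares_layout(self):
        rng = np.random.default_rng(11)
        G, L = dv.build_deviance_matrix(self.mk_summaries(rng), with_log_ratio=True)
        assert G.shape == L.shape
        assert list(G.index) == list(L.index)

    def test_deviance_stabilizes_rare_drugs_relative_to_log_ratio(self):
        # under the null, the log-ratio's spread blows up for rare drugs
        # while the deviance residual's spread stays comparable
        rng = np.random.default_rng(13)
        n, reps = 400.0, 2000
        rows = []
        for drug, p in (("rare", 0.004), ("common", 0.2)):
            y = rng.binomial(int(n), p, reps).astype(float)
            rows.append(pd.DataFrame({
                "drug_id": drug, "county_id": [f"c{i:04d}" for i in range(reps)],
                "n_w": n, "y_w": y, "yhat_w": n * p,
            }))
        G, L = dv.build_deviance_matrix(pd.concat(rows), with_log_ratio=True)
        ratio_logratio = L["rare"].std() / L["common"].std()
        ratio_deviance = G["rare"].std() / G["common"].std()
        assert ratio_logratio > 3 * ratio_deviance
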