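"""Endpoint construction, rank statistics, KM curves and Cox models."""

import numpy as np
import pandas as pd
import pytest

from crcimmune import PipelineConfig
from crcimmune.simulate import CohortSimSpec, simulate_cohort
from crcimmune.survival import (
    build_ttr,
    correlation_matrix,
    cox_fit,
    group_compare,
    km_quartiles,
    km_table,
    model_compare,
    ordinal_association,
    transform_scores,
)


class TestBuildTtr:
    @pytest.mark.parametrize(
        "months,event,exp_t,exp_e",
        [(72.0, 1, 60.0, 0), (24.0, 1, 24.0, 1), (40.0, 0, 40.0, 0),
         (60.0, 1, 60.0, 1), (61.0, 0, 60.0, 0)],
    )
    def test_five_year_rule(self, cfg, months, event, exp_t, exp_e):
        frame = pd.DataFrame({"followup_months": [months], "event": [event]})
        out = build_ttr(frame, cfg)
        assert out["ttr_months"].iloc[0] == exp_t
        assert out["ttr_event"].iloc[0] == exp_e

    def test_negative_followup_rejected(self, cfg):
        frame = pd.DataFrame({"followup_months": [-1.0], "event": [0]})
        with pytest.raises(ValueError, match="negative"):
            build_ttr(frame, cfg)

    def test_rule_holds_for_all_simulated_patients(self, cfg):
        frame, _ = simulate_cohort(CohortSimSpec(n_patients=400, rng_seed=3))
        out = build_ttr(frame, cfg)
        assert (out["ttr_months"] <= 60.0).all()
        late = frame["followup_months"] > 60.0
        assert (out.loc[late, "ttr_event"] == 0).all()
        early = ~late
        assert (out.loc[early, "ttr_event"] == frame.loc[early, "event"]).all()


class TestTransformScores:
    def test_values_and_monotonicity(self):
        frame = pd.DataFrame({"EosF": [0.0, np.e - 1, -0.5, 3.0], "IEL": [2.0] * 4})
        out = transform_scores(frame)
        assert out["EosF"].iloc[0] == 0.0
        assert out["EosF"].iloc[1] == pytest.approx(1.0)
        assert out["EosF"].iloc[2] == 0.0  # negatives floored at 0
        assert (out["IEL"] == 2.0).all()  # IEL untransformed
        x = np.sort(np.random.default_rng(0).uniform(0, 5, 50))
        t = transform_scores(pd.DataFrame({"LymF": x}))["LymF"].to_numpy()
        assert (np.diff(t) > 0).all()


class TestRankStatistics:
    def test_monotone_pairs(self):
        frame = pd.DataFrame({"a": np.arange(20.0), "b": np.arange(20.0) ** 3,
                              "c": -np.arange(20.0)})
        rho, p = correlation_matrix(frame, ["a", "b", "c"])
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(rho.values, rho.values.T)

    def test_independent_pair_small_rho(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        rho, _ = correlation_matrix(frame, ["a", "b"])
        assert abs(rho.loc["a", "b"]) < 0.1

    def test_insufficient_pairs_missing(self):
        frame = pd.DataFrame({"a": [1.0, np.nan, np.nan], "b": [np.nan, 2.0, 3.0]})
        rho, _ = correlation_matrix(frame, ["a", "b"])
        assert np.isnan(rho.loc["a", "b"])

    def test_kendall_staircase(self):
        score = np.repeat([1.0, 2.0, 3.0], 5)
        tau, _ = ordinal_association(score, np.repeat([1, 2, 3], 5))
        assert tau == pytest.approx(1.0)
        tau_rev, _ = ordinal_association(score, np.repeat([3, 2, 1], 5))
        assert tau_rev == pytest.approx(-1.0)

    def test_kendall_null_small(self):
        rng = np.random.default_rng(1)
        tau, _ = ordinal_association(rng.normal(size=500), rng.integers(0, 4, 500))
        assert abs(tau) < 0.1

    def test_mann_whitney_disjoint_and_identical(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(
            {"score": np.concatenate([rng.uniform(0, 1, 50), rng.uniform(5, 6, 50)]),
             "grp": ["lo"] * 50 + ["hi"] * 50}
        )
        res = group_compare(frame, "score", "grp")
        assert res["p"].iloc[0] < 1e-4
        same = pd.DataFrame({"score": np.tile(np.arange(30.0), 2),
                             "grp": ["a"] * 30 + ["b"] * 30})
        res2 = group_compare(same, "score", "grp")
        assert res2["p"].iloc[0] > 0.9

    def test_empty_group_raises(self):
        frame = pd.DataFrame({"score": [np.nan, 1.0], "grp": ["a", "b"]})
        with pytest.raises(ValueError, match="'a'"):
            group_compare(frame, "score", "grp")


class TestKaplanMeier:
    def test_product_limit_worked_example(self):
        """10 patients, hand-computed product-limit survival."""
        times = [2, 3, 3, 5, 6, 7, 8, 9, 10, 12]
        events = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
        # risk sets: t=2 n=10 d=1; t=3 n=9 d=1; t=5 n=7 d=1; t=7 n=5 d=1;
        #            t=8 n=4 d=1; t=10 n=2 d=1
        expected = {
            2: 9 / 10,
            3: (9 / 10) * (8 / 9),
            5: (9 / 10) * (8 / 9) * (6 / 7),
            7: (9 / 10) * (8 / 9) * (6 / 7) * (4 / 5),
            8: (9 / 10) * (8 / 9) * (6 / 7) * (4 / 5) * (3 / 4),
            10: (9 / 10) * (8 / 9) * (6 / 7) * (4 / 5) * (3 / 4) * (1 / 2),
        }
        table = km_table(times, events)
        for t, s in expected.items():
            row = table[table["time"] == t]
            assert row["survival"].iloc[0] == pytest.approx(s)

    def test_quartiles_protective_effect_orders_curves(self):
        rng = np.random.default_rng(4)
        n = 800
        score = rng.uniform(0, 1, n)
        rate = 0.05 * np.exp(-3.0 * score)  # strongly protective
        t = rng.exponential(1 / rate)
        c = rng.uniform(10, 80, n)
        frame = pd.DataFrame(
            {"score": score, "ttr_months": np.minimum(t, c), "ttr_event": (t <= c).astype(int)}
        )
        res = km_quartiles(frame, "score")
        finals = {
            q: res.curves[res.curves.quartile == q]["survival"].iloc[-1]
            for q in (1, 2, 3, 4)
        }
        assert finals[1] < finals[2] < finals[3] < finals[4]
        assert all(res.wald_p[q] < 0.01 for q in (2, 3, 4))

    def test_quartile_cuts_on_full_cohort_before_subset(self):
        rng = np.random.default_rng(5)
        n = 400
        frame = pd.DataFrame(
            {"score": rng.uniform(0, 1, n),
             "ttr_months": rng.uniform(1, 60, n),
             "ttr_event": rng.integers(0, 2, n),
             "msi": rng.integers(0, 2, n)}
        )
        full = km_quartiles(frame, "score")
        sub = km_quartiles(frame, "score", subset=frame["msi"] == 1)
        assert np.allclose(full.cut_points, sub.cut_points)
        assert sum(sub.n_per_quartile.values()) == int((frame["msi"] == 1).sum())

    def test_constant_score_raises(self):
        frame = pd.DataFrame(
            {"score": np.ones(40), "ttr_months": np.arange(1.0, 41.0),
             "ttr_event": [1, 0] * 20}
        )
        with pytest.raises(ValueError, match="score"):
            km_quartiles(frame, "score")


class TestCox:
    def test_identical_groups_null_hr(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(20, 200)
        frame = pd.DataFrame(
            {"ttr_months": np.tile(t, 2), "ttr_event": 1,
             "x": np.repeat([0.0, 1.0], 200)}
        )
        res = cox_fit(frame, ["x"], check_ph=False)
        assert res.hr("x") == pytest.approx(1.0, abs=1e-6)
        assert res.p("x") > 0.99
        lo, hi = res.ci("x")
        assert lo <= 1.0 <= hi

    def test_nested_model_likelihood_monotone(self):
        frame, _ = simulate_cohort(CohortSimSpec(n_patients=300, rng_seed=7))
        frame = transform_scores(build_ttr(frame))
        small = cox_fit(frame, ["EosF"], check_ph=False)
        big = cox_fit(frame, ["EosF", "LymF", "IEL"], check_ph=False)
        assert big.log_likelihood >= small.log_likelihood
        assert big.aic == pytest.approx(2 * 3 - 2 * big.log_likelihood)

    def test_missing_rows_dropped_and_counted(self):
        frame, _ = simulate_cohort(CohortSimSpec(n_patients=200, rng_seed=8))
        frame = transform_scores(build_ttr(frame))
        frame.loc[frame.index[:17], "EosF"] = np.nan
        res = cox_fit(frame, ["EosF"], check_ph=False)
        assert res.n_dropped == 17 and res.n == 183

    def test_model_compare_requires_same_subset(self):
        frame, _ = simulate_cohort(CohortSimSpec(n_patients=300, rng_seed=9))
        frame = transform_scores(build_ttr(frame))
        a = cox_fit(frame, ["EosF"], check_ph=False)
        b = cox_fit(frame.iloc[:200], ["LymF"], check_ph=False)
        with pytest.raises(ValueError, match="subset"):
            model_compare({"a": a, "b": b})

    def test_model_compare_ranking(self):
        frame, _ = simulate_cohort(CohortSimSpec(n_patients=400, rng_seed=10))
        frame = transform_scores(build_ttr(frame))
        a = cox_fit(frame, ["EosF"], check_ph=False)
        b = cox_fit(frame, ["EosF", "IEL"], check_ph=False)
        out = model_compare({"EosF": a, "EosF+IEL": b})
        assert out["delta_aic"].iloc[0] == 0.0
        assert (out["delta_aic"] >= 0).all()
        assert list(out["aic"]) == sorted(out["aic"])

    def test_ph_diagnostic_reported(self):
        frame, _ = simulate_cohort(CohortSimSpec(n_patients=300, rng_seed=11))
        frame = transform_scores(build_ttr(frame))
        res = cox_fit(frame, ["EosF"], check_ph=True)
        assert "EosF" in res.ph_test_p
        assert 0.0 <= res.ph_test_p["EosF"] <= 1.0
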