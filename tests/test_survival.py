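import math

import numpy as np
import pytest

import tmtvkit as tk
from tmtvkit.errors import DegenerateDataError
from tmtvkit.survival import records_to_frame


def make_records(times, events, tmtv):
    return [
        tk.SurvivalRecord(f"S{i}", float(t), int(e), float(v))
        for i, (t, e, v) in enumerate(zip(times, events, tmtv))
    ]


def simulated_cohort(n, hr, seed, censor=8.0):
    model = tk.SurvivalModelSpec(hazard_ratio=hr, cutoff_cm3=100.0, censor_time_years=censor)
    rng = np.random.default_rng(seed)
    tmtv = rng.uniform(10.0, 400.0, n)
    return tk.simulate_survival(tmtv, model, seed=seed + 1)


def efron_loglik(time, event, x, beta):
    """Independent Efron partial log-likelihood for the score-residual check."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    eta = beta * x
    ll = 0.0
    for te in np.unique(time[event == 1]):
        deaths = (time == te) & (event == 1)
        at_risk = time >= te
        dk = int(deaths.sum())
        s0 = np.sum(np.exp(eta[at_risk]))
        d0 = np.sum(np.exp(eta[deaths]))
        ll += float(np.sum(eta[deaths]))
        for j in range(dk):
            ll -= math.log(s0 - j / dk * d0)
    return ll


class TestFourYearRoc:
    def test_perfect_separation_auc_one_cutoff_between_groups(self):
        times = [1.0] * 10 + [6.0] * 10
        events = [1] * 10 + [0] * 10
        tmtv = list(np.linspace(300, 400, 10)) + list(np.linspace(10, 100, 10))
        res = tk.four_year_roc(make_records(times, events, tmtv))
        assert res.auc == pytest.approx(1.0)
        assert 100.0 <= res.youden_optimal_cutoff < 300.0

    def test_uninformative_marker_auc_near_half(self):
        recs = simulated_cohort(2000, hr=1.0, seed=5)
        res = tk.four_year_roc(recs)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_naive_equals_km_weighted_without_censoring(self):
        recs = simulated_cohort(300, hr=2.0, seed=2, censor=1e9)
        a = tk.four_year_roc(recs, method="km_weighted")
        b = tk.four_year_roc(recs, method="naive")
        np.testing.assert_allclose(
            a.points[["sensitivity", "specificity"]], b.points[["sensitivity", "specificity"]]
        )
        assert a.auc == pytest.approx(b.auc)
        assert a.youden_optimal_cutoff == b.youden_optimal_cutoff

    def test_auc_invariant_under_monotone_marker_transform(self):
        recs = simulated_cohort(400, hr=2.5, seed=3)
        df = records_to_frame(recs)
        base = tk.four_year_roc(df)
        df2 = df.assign(tmtv_cm3=np.log1p(df["tmtv_cm3"]) ** 3)
        trans = tk.four_year_roc(df2)
        assert trans.auc == pytest.approx(base.auc, abs=1e-12)

    def test_youden_cutoff_equals_bruteforce_maximum(self):
        recs = simulated_cohort(200, hr=2.5, seed=9, censor=1e9)
        df = records_to_frame(recs)
        res = tk.four_year_roc(df, method="naive")
        # exhaustive independent search over observed cutoffs
        cases = df[(df.event == 1) & (df.time_years <= 4.0)]["tmtv_cm3"].to_numpy()
        ctrls = df[df.time_years > 4.0]["tmtv_cm3"].to_numpy()
        best_j, best_c = -np.inf, None
        for c in sorted(df["tmtv_cm3"].unique()):
            j = (cases > c).mean() + (ctrls <= c).mean() - 1.0
            if j > best_j + 1e-15:
                best_j, best_c = j, c
        assert res.youden_optimal_cutoff == best_c

    def test_no_events_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            tk.four_year_roc(make_records([5, 6, 7], [0, 0, 0], [10, 20, 30]))


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        recs = make_records(times, [1] * 10, [0] * 10)
        km = tk.km_estimate(recs, ["all"] * 10)["all"]
        assert tk.km_rate_at(km, 5.0) == pytest.approx(0.5)
        for t in times:
            emp = np.mean(np.asarray(times) > t)
            assert tk.km_rate_at(km, t) == pytest.approx(emp)

    def test_no_events_survival_stays_one(self):
        recs = make_records([2, 3, 4], [0, 0, 0], [0, 0, 0])
        km = tk.km_estimate(recs, ["g"] * 3)["g"]
        assert tk.km_rate_at(km, 4.0) == 1.0

    def test_product_limit_hand_example(self):
        # times {1, 2+, 3}, events {1, 0, 1}: S(3) = (1 - 1/3)(1 - 1/1) = 0
        recs = make_records([1, 2, 3], [1, 0, 1], [0, 0, 0])
        km = tk.km_estimate(recs, ["g"] * 3)["g"]
        assert tk.km_rate_at(km, 1.0) == pytest.approx(2 / 3)
        assert tk.km_rate_at(km, 3.0) == pytest.approx(0.0)


class TestLogRank:
    def test_identical_groups_give_no_signal(self):
        times = [1, 2, 3, 4, 5]
        recs = make_records(times * 2, [1, 0, 1, 1, 0] * 2, [0] * 10)
        chi2, p = tk.logrank_test(recs, ["a"] * 5 + ["b"] * 5)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_strongly_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        t_a = rng.exponential(1.0, 250)
        t_b = rng.exponential(5.0, 250)
        recs = make_records(np.r_[t_a, t_b], [1] * 500, [0] * 500)
        _chi2, p = tk.logrank_test(recs, ["a"] * 250 + ["b"] * 250)
        assert p < 1e-3


class TestCox:
    def test_identical_event_patterns_give_unit_hazard_ratio(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 0, 1, 1, 0, 1]
        recs = make_records(times * 2, events * 2, [0] * 12)
        hr, lo, hi, _p = tk.cox_univariate(recs, [0] * 6 + [1] * 6)
        assert hr == pytest.approx(1.0, abs=1e-6)
        assert lo < 1.0 < hi

    def test_efron_and_breslow_agree_without_ties(self):
        rng = np.random.default_rng(4)
        n = 150
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.1 * np.exp(math.log(2.0) * x)))
        t += rng.uniform(0, 1e-6, n)  # ensure no exact ties
        recs = make_records(t, [1] * n, [0] * n)
        hr_e, *_ = tk.cox_univariate(recs, x, ties="efron")
        hr_b, *_ = tk.cox_univariate(recs, x, ties="breslow")
        assert hr_e == pytest.approx(hr_b, abs=1e-5)

    def test_score_residual_small_at_estimate(self):
        recs = simulated_cohort(400, hr=2.5, seed=6)
        df = records_to_frame(recs)
        x = (df["tmtv_cm3"] > 100.0).astype(float).to_numpy()
        hr, *_ = tk.cox_univariate(df, x)
        beta = math.log(hr)
        h = 1e-5
        score = (
            efron_loglik(df.time_years, df.event, x, beta + h)
            - efron_loglik(df.time_years, df.event, x, beta - h)
        ) / (2 * h)
        assert abs(score) < 1e-3  # score equation holds at the optimum

    def test_single_level_covariate_rejected(self):
        recs = make_records([1, 2, 3], [1, 1, 0], [5, 5, 5])
        with pytest.raises(DegenerateDataError):
            tk.cox_univariate(recs, [1, 1, 1])


class TestPrognosticModel:
    def test_scaling_tmtv_scales_cutoff_but_not_auc_hr_p(self):
        recs = simulated_cohort(400, hr=2.5, seed=8)
        df = records_to_frame(recs)
        res1 = tk.PrognosticModel(df).fit()
        res2 = tk.PrognosticModel(df.assign(tmtv_cm3=2.0 * df["tmtv_cm3"])).fit()
        assert res2.comparison.cutoff_cm3 == pytest.approx(2.0 * res1.comparison.cutoff_cm3)
        assert res2.roc.auc == pytest.approx(res1.roc.auc, abs=1e-12)
        assert res2.comparison.hazard_ratio == pytest.approx(res1.comparison.hazard_ratio, rel=1e-9)
        assert res2.comparison.logrank_p == pytest.approx(res1.comparison.logrank_p, rel=1e-9)

    def test_constant_tmtv_is_degenerate(self):
        recs = make_records([1, 2, 3, 4], [1, 1, 0, 0], [100, 100, 100, 100])
        with pytest.raises(DegenerateDataError):
            tk.PrognosticModel(recs).fit()

    def test_summary_has_table_shape(self):
        recs = simulated_cohort(300, hr=2.5, seed=10)
        res = tk.run_prognostic_analysis(recs, endpoint="PFS")
        tab = res.summary()
        for col in ("auc", "cutoff_cm3", "hazard_ratio", "logrank_p"):
            assert col in tab.columns
        d = res.to_dict()
        assert d["endpoint"] == "PFS"
        assert d["hr_ci"][0] <= d["hazard_ratio"] <= d["hr_ci"][1]
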