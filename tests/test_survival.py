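import numpy as np
import pandas as pd
import pytest

from scapa import (
    SurvivalSimConfig,
    administrative_censor,
    cox_multivariate,
    km_estimate,
    logrank_test,
    quartile_groups,
    simulate_survival,
    stage_class,
)


def _records(times, events, **cov):
    return pd.DataFrame({"time": times, "event": events, **cov},
                        index=[f"p{i}" for i in range(len(times))])


class TestAdministrativeCensor:
    def test_death_beyond_horizon_becomes_survivor(self):
        out = administrative_censor(_records([12.0], [1]))
        assert out.loc["p0", "time"] == 10.0
        assert out.loc["p0", "event"] == 0

    def test_early_death_unchanged(self):
        out = administrative_censor(_records([6.0, 12.0], [1, 0]))
        assert out.loc["p0", "time"] == 6.0 and out.loc["p0", "event"] == 1
        assert out.loc["p1", "time"] == 10.0 and out.loc["p1", "event"] == 0

    def test_idempotent(self):
        rec = _records([3.0, 9.9, 10.0, 25.0], [1, 1, 1, 1])
        once = administrative_censor(rec)
        pd.testing.assert_frame_equal(administrative_censor(once), once)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            administrative_censor(_records([-1.0], [1]))


class TestQuartileGroups:
    def test_interpolated_quartiles_on_1_to_8(self):
        vals = pd.Series(np.arange(1.0, 9.0), index=[f"p{i}" for i in range(8)])
        groups = quartile_groups(vals)
        assert set(vals.index[groups == "low"]) == {"p0", "p1"}
        assert set(vals.index[groups == "high"]) == {"p6", "p7"}
        assert (groups == "excluded").sum() == 4

    def test_constant_expression_excludes_everyone(self):
        groups = quartile_groups(pd.Series([2.0] * 6))
        assert (groups == "excluded").all()

    def test_four_distinct_values_give_one_low_one_high(self):
        groups = quartile_groups(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert (groups == "low").sum() == 1
        assert (groups == "high").sum() == 1

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            quartile_groups(pd.Series([1.0, 2.0, 3.0]))


def test_stage_class_maps_early_and_late():
    stages = pd.Series(["Stage I", "Stage IIA", "stage iii", "Stage IV", None])
    out = stage_class(stages)
    assert out.tolist()[:4] == ["early", "early", "late", "late"]
    assert pd.isna(out.iloc[4])


class TestKaplanMeier:
    def test_survival_starts_at_one(self):
        curve = km_estimate([5.0], [1])
        assert curve.survival_at(0.0) == 1.0

    def test_hand_product_limit(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.survival_at(2.5) == pytest.approx(0.5)
        assert curve.survival_at(4.0) == pytest.approx(0.0)

    def test_censoring_shrinks_risk_set_without_a_factor(self):
        curve = km_estimate([1.0, 2.0], [0, 1])
        assert curve.survival_at(2.0) == pytest.approx(0.0)
        assert curve.times.tolist() == [2.0]
        assert curve.at_risk.tolist() == [1]

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(5.0, size=40)
        curve = km_estimate(times, np.ones(40, dtype=int))
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        times = np.round(rng.exponential(5.0, size=60), 1)
        events = (rng.random(60) < 0.7).astype(int)
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]))


class TestLogrank:
    def test_identical_groups_are_null(self):
        chi2, p = logrank_test([1, 2, 3, 4], [1, 1, 0, 1],
                               [1, 2, 3, 4], [1, 1, 0, 1])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self, rng):
        t1 = rng.exponential(5, 30); e1 = (rng.random(30) < 0.8).astype(int)
        t2 = rng.exponential(3, 25); e2 = (rng.random(25) < 0.8).astype(int)
        a = logrank_test(t1, e1, t2, e2)
        b = logrank_test(t2, e2, t1, e1)
        assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])

    def test_zero_events_is_an_error(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank
        t1 = np.round(rng.exponential(5, 50), 1)
        e1 = (rng.random(50) < 0.7).astype(int)
        t2 = np.round(rng.exponential(3, 40), 1)
        e2 = (rng.random(40) < 0.7).astype(int)
        chi2, p = logrank_test(t1, e1, t2, e2)
        ref = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_null_type_one_error_near_nominal(self):
        rejections = 0
        n_reps = 120
        for seed in range(n_reps):
            config = SurvivalSimConfig(n_patients=80, log_hazard_ratio=0.0,
                                       seed=seed)
            group = np.arange(80) % 2
            rec = simulate_survival(config, group)
            g1 = rec[rec["group"] == 1]
            g0 = rec[rec["group"] == 0]
            _, p = logrank_test(g1["time"], g1["event"],
                                g0["time"], g0["event"])
            rejections += p < 0.05
        assert 0.005 < rejections / n_reps < 0.12


class TestCox:
    def test_constant_covariate_rejected(self):
        rec = _records([1, 2, 3, 4], [1, 1, 1, 1], x=[1, 1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            cox_multivariate(rec, ["x"])

    def test_collinear_design_is_flagged_not_silent(self, rng):
        n = 40
        x = rng.normal(size=n)
        rec = _records(rng.exponential(5, n), np.ones(n, dtype=int),
                       x=x, x_copy=2 * x)
        result = cox_multivariate(rec, ["x", "x_copy"])
        assert not result.success
        assert "collinear" in result.message

    def test_more_covariates_than_events_refused(self, rng):
        rec = _records([1, 2, 3, 4], [1, 0, 0, 0],
                       a=[1, 2, 3, 4], b=[4, 1, 2, 2])
        with pytest.raises(ValueError, match="events"):
            cox_multivariate(rec, ["a", "b"])

    def test_null_group_estimate_within_three_se(self):
        config = SurvivalSimConfig(n_patients=300, log_hazard_ratio=0.0, seed=21)
        group = np.arange(300) % 2
        rec = simulate_survival(config, group)
        result = cox_multivariate(rec, ["group", "age"])
        assert result.success
        coef = result.summary.loc["group", "coef"]
        se = result.summary.loc["group", "se"]
        assert abs(coef) < 3 * se
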