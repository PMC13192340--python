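import math

import numpy as np
import pytest

from popmortgen.popmort_engine import build_popmort
from popmortgen.relative_survival import (
    CohortRecord,
    RSEstimate,
    age_standardised_rs,
    expected_survival_ederer2,
    observed_survival,
    relative_survival,
)
from popmortgen.synthetic_fixtures import SyntheticParams, make_life_table, simulate_cohort


def _rec(time, event, sex=1, year=2015, age=60, id=0):
    return CohortRecord(id=id, sex=sex, entry_year=year, entry_age=age,
                        time_years=time, event=event)


def _flat_popmort(rate, start=2010, end=2025):
    """PopMort with one constant rate everywhere (constant hazard)."""
    mu = rate
    p = SyntheticParams(makeham_a=mu, gompertz_b=0.0)
    tables = [make_life_table(p, (2016, 2020), s, sex_scale=1.0) for s in (1, 2)]
    pm = build_popmort(tables, start, end)
    if mu == 0.0:
        return pm
    # overwrite with the exact rate so annual prob is exactly exp(-rate)
    pm.frame["rate"] = mu
    pm.frame["prob"] = math.exp(-mu)
    return pm


class TestCohortRecord:
    def test_invalid_sex(self):
        with pytest.raises(ValueError):
            _rec(1.0, 0, sex=0)

    def test_negative_time(self):
        with pytest.raises(ValueError):
            _rec(-1.0, 0)

    def test_invalid_event(self):
        with pytest.raises(ValueError):
            CohortRecord(id=0, sex=1, entry_year=2015, entry_age=60,
                         time_years=1.0, event=2)


class TestObservedSurvival:
    def test_no_deaths(self):
        cohort = [_rec(5.0, 0, id=i) for i in range(10)]
        surv, _ = observed_survival(cohort, 1, 5)
        assert np.allclose(surv, 1.0)

    def test_two_deaths_of_ten(self):
        cohort = [_rec(0.5, 1, id=0), _rec(0.7, 1, id=1)] + [
            _rec(5.0, 0, id=i) for i in range(2, 10)
        ]
        surv, _ = observed_survival(cohort, 1, 5)
        assert surv[0] == pytest.approx(0.8)

    def test_half_censoring_correction(self):
        # 1 death, 2 censored in interval 1: n_eff = 10 - 2/2 = 9
        cohort = (
            [_rec(0.5, 1, id=0), _rec(0.3, 0, id=1), _rec(0.6, 0, id=2)]
            + [_rec(5.0, 0, id=i) for i in range(3, 10)]
        )
        surv, _ = observed_survival(cohort, 1, 5)
        assert surv[0] == pytest.approx(1 - 1 / 9)

    def test_cumulative_product(self):
        # 1 of 4 dies in interval 1, 1 of 3 in interval 2
        cohort = [_rec(0.5, 1, id=0), _rec(1.5, 1, id=1),
                  _rec(5.0, 0, id=2), _rec(5.0, 0, id=3)]
        surv, _ = observed_survival(cohort, 1, 5)
        assert surv[0] == pytest.approx(0.75)
        assert surv[1] == pytest.approx(0.75 * (1 - 1 / 3))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            observed_survival([], 1, 5)

    def test_greenwood_accumulates(self):
        cohort = [_rec(0.5, 1, id=0)] + [_rec(5.0, 0, id=i) for i in range(1, 10)]
        _, gw = observed_survival(cohort, 1, 5)
        assert gw[0] == pytest.approx(1 / (10 * 9))
        assert gw[4] == gw[0]  # no later deaths


class TestEderer2:
    def test_all_prob_one(self):
        pm = _flat_popmort(0.0)
        cohort = [_rec(5.0, 0, id=i) for i in range(5)]
        exp = expected_survival_ederer2(cohort, pm, 1, 5)
        assert np.allclose(exp, 1.0)

    def test_single_patient_power_law(self):
        rate = -math.log(0.98)
        pm = _flat_popmort(rate)
        cohort = [_rec(5.0, 0)]
        exp = expected_survival_ederer2(cohort, pm, 1, 5)
        for k in range(1, 6):
            assert exp[k - 1] == pytest.approx(0.98 ** k, rel=1e-12)
        assert exp[4] == pytest.approx(0.9039207968, rel=1e-9)

    def test_risk_set_mean(self):
        # two patients at different ages -> interval-1 expectation is the mean
        pm = _flat_popmort(0.05)
        # craft one patient at prob exp(-0.05) and modify one cell to prob 1.0
        pm.frame.loc[
            (pm.frame["year"] == 2015) & (pm.frame["sex"] == 1)
            & (pm.frame["age"] == 40), ["rate", "prob"]
        ] = [0.0, 1.0]
        cohort = [_rec(5.0, 0, age=60, id=0), _rec(5.0, 0, age=40, id=1)]
        exp = expected_survival_ederer2(cohort, pm, 1, 5)
        assert exp[0] == pytest.approx((math.exp(-0.05) + 1.0) / 2, rel=1e-12)

    def test_risk_set_shrinks(self):
        pm = _flat_popmort(0.05)
        pm.frame.loc[
            (pm.frame["year"].isin([2016, 2017])) & (pm.frame["sex"] == 1)
            & (pm.frame["age"].isin([41, 42])), ["rate", "prob"]
        ] = [0.0, 1.0]
        # patient 1 exits after year 1; only patient 0 contributes later
        cohort = [_rec(5.0, 0, age=60, id=0), _rec(1.0, 0, age=40, id=1)]
        exp = expected_survival_ederer2(cohort, pm, 1, 5)
        p = math.exp(-0.05)
        assert exp[0] == pytest.approx(p, rel=1e-12)  # both share prob in year 1
        assert exp[1] == pytest.approx(p * p, rel=1e-12)  # only patient 0 remains

    def test_order_invariance(self):
        pm = _flat_popmort(0.03)
        cohort = [_rec(5.0, 0, age=50 + i, id=i) for i in range(6)]
        a = expected_survival_ederer2(cohort, pm, 1, 5)
        b = expected_survival_ederer2(list(reversed(cohort)), pm, 1, 5)
        assert np.allclose(a, b, rtol=1e-14)

    def test_non_increasing(self):
        pm = _flat_popmort(0.03)
        cohort = [_rec(5.0, 0, age=50 + i, id=i) for i in range(6)]
        exp = expected_survival_ederer2(cohort, pm, 1, 5)
        assert all(b <= a for a, b in zip(exp, exp[1:]))

    def test_coverage_gap_reported(self):
        pm = _flat_popmort(0.03, start=2014, end=2016)
        cohort = [_rec(5.0, 0, year=2015)]
        with pytest.raises(ValueError, match="cover"):
            expected_survival_ederer2(cohort, pm, 1, 5)

    def test_age_capped_at_popmort_max(self):
        pm = _flat_popmort(0.03)
        cohort = [_rec(5.0, 0, age=99)]
        exp = expected_survival_ederer2(cohort, pm, 1, 5)
        assert exp[4] == pytest.approx(math.exp(-0.03 * 5), rel=1e-12)


class TestRelativeSurvival:
    def test_rs_one_when_observed_equals_expected(self):
        # no deaths and prob = 1 popmort
        pm = _flat_popmort(0.0)
        cohort = [_rec(5.0, 0, id=i) for i in range(20)]
        for est in relative_survival(cohort, pm, 1, 5):
            assert est.relative == pytest.approx(1.0)
            assert est.ci_low <= 1.0 <= est.ci_high

    def test_zero_popmort_rates_make_rs_equal_observed(self):
        pm = _flat_popmort(0.0)
        cohort = [_rec(0.5, 1, id=0), _rec(1.5, 1, id=1)] + [
            _rec(5.0, 0, id=i) for i in range(2, 10)
        ]
        obs, _ = observed_survival(cohort, 1, 5)
        ests = relative_survival(cohort, pm, 1, 5)
        for est, s in zip(ests, obs):
            assert est.relative == pytest.approx(s, rel=1e-14)

    def test_ci_brackets_estimate(self):
        pm = _flat_popmort(0.02)
        cohort = [_rec(0.5, 1, id=0), _rec(2.5, 1, id=1)] + [
            _rec(5.0, 0, id=i) for i in range(2, 30)
        ]
        for est in relative_survival(cohort, pm, 1, 5):
            assert est.ci_low <= est.relative <= est.ci_high

    def test_excess_hazard_lowers_rs(self):
        p0 = SyntheticParams(seed=13, cohort_n=4000, excess_hazard=0.05,
                             entry_year_range=(2012, 2014),
                             entry_age_range=(50, 70), follow_up_years=5)
        p1 = SyntheticParams(seed=13, cohort_n=4000, excess_hazard=0.10,
                             entry_year_range=(2012, 2014),
                             entry_age_range=(50, 70), follow_up_years=5)
        tables = [make_life_table(p0, (2016, 2020), s) for s in (1, 2)]
        pm = build_popmort(tables, 2010, 2020)
        rs_a = relative_survival(simulate_cohort(pm, p0), pm, 1, 5)
        rs_b = relative_survival(simulate_cohort(pm, p1), pm, 1, 5)
        assert rs_b[4].relative < rs_a[4].relative < 1.0

    def test_null_cohort_rs_near_one(self):
        p = SyntheticParams(seed=21, cohort_n=10000, excess_hazard=0.0,
                            entry_year_range=(2012, 2014),
                            entry_age_range=(50, 75), follow_up_years=5)
        tables = [make_life_table(p, (2016, 2020), s) for s in (1, 2)]
        pm = build_popmort(tables, 2010, 2020)
        cohort = simulate_cohort(pm, p)
        for est in relative_survival(cohort, pm, 1, 5):
            se = math.sqrt(est.variance)
            assert abs(est.relative - 1.0) < 3 * se + 1e-9


class TestRSEstimate:
    def test_ratio_enforced(self):
        with pytest.raises(ValueError, match="observed / expected"):
            RSEstimate(interval_end=1, observed=0.9, expected=0.95,
                       relative=0.5, ci_low=0.4, ci_high=0.6)

    def test_ci_ordering_enforced(self):
        with pytest.raises(ValueError, match="CI"):
            RSEstimate(interval_end=1, observed=0.9, expected=0.9,
                       relative=1.0, ci_low=1.1, ci_high=1.2)


def _est(rs, interval_end=1.0, expected=0.9, var=0.0001):
    half = 1.959963984540054 * math.sqrt(var)
    return RSEstimate(interval_end=interval_end, observed=rs * expected,
                      expected=expected, relative=rs, ci_low=rs - half,
                      ci_high=rs + half, variance=var)


class TestAgeStandardisedRS:
    def test_identical_groups_any_weights(self):
        groups = {"a": [_est(0.8)], "b": [_est(0.8)], "c": [_est(0.8)]}
        for weights in ({"a": 1, "b": 1, "c": 1}, {"a": 0.7, "b": 0.2, "c": 0.1},
                        {"a": 5, "b": 3, "c": 2}):
            out = age_standardised_rs(groups, weights)
            assert out[0].relative == pytest.approx(0.8, rel=1e-12)

    def test_weighted_mean(self):
        groups = {"young": [_est(0.4)], "old": [_est(0.6)]}
        out = age_standardised_rs(groups, {"young": 0.5, "old": 0.5})
        assert out[0].relative == pytest.approx(0.5)

    def test_single_group_degenerate(self):
        groups = {"only": [_est(0.73)]}
        out = age_standardised_rs(groups, {"only": 1.0})
        assert out[0].relative == pytest.approx(0.73)

    def test_empty_group_dropped_with_warning(self):
        groups = {"a": [_est(0.4)], "b": []}
        with pytest.warns(UserWarning, match="dropping"):
            out = age_standardised_rs(groups, {"a": 0.5, "b": 0.5})
        assert out[0].relative == pytest.approx(0.4)

    def test_variance_combination(self):
        groups = {"a": [_est(0.4, var=0.01)], "b": [_est(0.6, var=0.04)]}
        out = age_standardised_rs(groups, {"a": 0.5, "b": 0.5})
        assert out[0].variance == pytest.approx(0.25 * 0.01 + 0.25 * 0.04)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            age_standardised_rs({"a": [_est(0.5)]}, {"a": -1.0})

    def test_mismatched_intervals_rejected(self):
        groups = {"a": [_est(0.5)], "b": [_est(0.5), _est(0.4, interval_end=2.0)]}
        with pytest.raises(ValueError, match="same number"):
            age_standardised_rs(groups, {"a": 0.5, "b": 0.5})
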