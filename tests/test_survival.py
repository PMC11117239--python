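"""Kaplan-Meier estimation: product-limit values, Greenwood log-log bands,
medians, and the malignancy-by-treatment grouping."""

import dataclasses

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from scipy.stats import norm

from lizonc import survival
from lizonc.cohort import (
    CaseRecord, Cohort, LifeStage, Malignancy, Metastasis, Outcome, Sex,
    Source, TreatmentCategory,
)
from lizonc.survival import greenwood_ci, km_estimate, median_survival


class TestProductLimit:
    def test_all_events_no_censoring(self):
        curve = km_estimate([1, 2, 3], [True, True, True])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.n_at_risk, [3, 2, 1])

    def test_middle_censored_hand_oracle(self):
        # events at 1 and 3, censoring at 2: S(1)=2/3, S(3)=0
        curve = km_estimate([1, 2, 3], [True, False, True])
        assert curve.survival_at(1) == pytest.approx(2 / 3, abs=1e-12)
        assert curve.survival_at(3) == pytest.approx(0.0, abs=1e-12)

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([5, 8, 13], [False, False, False])
        np.testing.assert_array_equal(curve.survival, 1.0)
        np.testing.assert_array_equal(curve.censor_marks, [5, 8, 13])

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        times = rng.integers(0, 20, 40).astype(float)
        curve = km_estimate(times, np.ones(40, dtype=bool))
        for t in np.unique(times):
            ecdf = np.mean(times <= t)
            assert curve.survival_at(t) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_ties_process_deaths_before_censorings(self):
        # at t=2: n=2 at risk, 1 death then 1 censoring -> S(2) = 1/2 * 1/2...
        # with death first, S(2) = S(1) * (1 - 1/2)
        curve = km_estimate([1, 2, 2], [True, True, False])
        assert curve.survival_at(2) == pytest.approx((2 / 3) * (1 / 2), abs=1e-12)

    def test_moving_a_late_censoring_later_changes_nothing(self):
        # a subject censored after the last event contributes the same risk
        # sets wherever its censoring time lies beyond that event
        base = km_estimate([1, 2, 3], [True, True, False])
        moved = km_estimate([1, 2, 99], [True, True, False])
        for t in (1, 2):
            assert moved.survival_at(t) == pytest.approx(
                base.survival_at(t), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestGreenwood:
    def test_no_events_zero_variance_band_collapses(self):
        curve = greenwood_ci(km_estimate([4, 5], [False, False]))
        np.testing.assert_array_equal(curve.variance, 0.0)
        np.testing.assert_array_equal(curve.ci_lower, 1.0)
        np.testing.assert_array_equal(curve.ci_upper, 1.0)

    def test_formula_oracle_ten_records(self, rng):
        times = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
        events = np.array([1, 1, 0, 1, 0, 1, 1, 0, 1, 0], dtype=bool)
        curve = greenwood_ci(km_estimate(times, events))
        # direct evaluation: exp(-exp(log(-log S) +- z*sqrt(V)/|log S|))
        z = norm.ppf(0.975)
        n, d = 10, 0
        at_risk = 10
        S, V = 1.0, 0.0
        for t, e in zip(times, events):
            if e:
                S *= 1 - 1 / at_risk
                V += 1 / (at_risk * (at_risk - 1)) if at_risk > 1 else 0.0
            at_risk -= 1
            if 0 < S < 1:
                se = np.sqrt(V) / abs(np.log(S))
                lo = np.exp(-np.exp(np.log(-np.log(S)) + z * se))
                hi = np.exp(-np.exp(np.log(-np.log(S)) - z * se))
                i = list(curve.times).index(t)
                assert curve.survival[i] == pytest.approx(S, abs=1e-12)
                assert curve.ci_lower[i] == pytest.approx(lo, abs=1e-10)
                assert curve.ci_upper[i] == pytest.approx(hi, abs=1e-10)

    def test_matches_lifelines_band(self, rng):
        times = rng.exponential(10, 30)
        events = rng.random(30) < 0.7
        curve = greenwood_ci(km_estimate(times, events))
        kmf = KaplanMeierFitter()
        kmf.fit(times, events)
        ci = kmf.confidence_interval_
        for i, t in enumerate(curve.times):
            if 0 < curve.survival[i] < 1:
                row = ci.loc[t]
                assert curve.ci_lower[i] == pytest.approx(row.iloc[0], abs=1e-8)
                assert curve.ci_upper[i] == pytest.approx(row.iloc[1], abs=1e-8)

    def test_bands_widen_as_sample_shrinks(self):
        # quadrupling every observation preserves S but narrows the band
        times = [1, 2, 3, 4]
        events = [True, True, False, True]
        small = greenwood_ci(km_estimate(times, events))
        big = greenwood_ci(km_estimate(times * 4, events * 4))
        np.testing.assert_allclose(small.survival, big.survival, atol=1e-12)
        interior = (small.survival > 0) & (small.survival < 1)
        assert np.all(
            (small.ci_upper - small.ci_lower)[interior]
            > (big.ci_upper - big.ci_lower)[interior]
        )

    def test_bounds_bracket_estimate_within_unit_interval(self, rng):
        times = rng.exponential(5, 25)
        events = rng.random(25) < 0.5
        curve = greenwood_ci(km_estimate(times, events))
        assert np.all(curve.ci_lower >= 0) and np.all(curve.ci_upper <= 1)
        assert np.all(curve.ci_lower <= curve.survival + 1e-12)
        assert np.all(curve.survival <= curve.ci_upper + 1e-12)


class TestMedian:
    def test_undefined_when_curve_stays_high(self):
        curve = km_estimate([1, 2, 3, 4], [True, False, False, False])
        assert median_survival(curve) is None

    def test_single_immediate_event(self):
        assert median_survival(km_estimate([0], [True])) == 0.0

    def test_matches_step_function_scan(self, rng):
        times = rng.integers(0, 12, 8).astype(float)
        events = rng.random(8) < 0.8
        curve = km_estimate(times, events)
        scan = None
        for t, s in zip(curve.times, curve.survival):
            if s <= 0.5:
                scan = float(t)
                break
        assert median_survival(curve) == scan

    def test_agrees_with_lifelines(self, rng):
        times = rng.exponential(8, 30)
        events = rng.random(30) < 0.7
        kmf = KaplanMeierFitter().fit(times, events)
        expected = kmf.median_survival_time_
        got = median_survival(km_estimate(times, events))
        if np.isinf(expected):
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)


def _case(i, malignancy, treatment, outcome, months):
    return CaseRecord(
        record_id=f"S{i}", source=Source.escra, species_common="x",
        species_scientific="Pogona vitticeps", age_months=None,
        life_stage=LifeStage.adult, sex=Sex.unknown, diagnosis="sarcoma",
        malignancy=malignancy, metastasis=Metastasis.unknown,
        tumor_location="skin", treatment=treatment, outcome=outcome,
        survival_months=months,
    )


class TestGroupSurvival:
    def test_single_group_cohort_yields_one_curve(self):
        cohort = Cohort([
            _case(i, Malignancy.benign, TreatmentCategory.surgery_only,
                  Outcome.died_neoplasia, float(i + 1))
            for i in range(4)
        ])
        grouped = survival.group_survival(cohort)
        assert list(grouped.curves) == [("benign", "neoplasia_with_treatment")]

    def test_group_sizes_conserve_known_survival_records(self):
        records = [
            _case(0, Malignancy.malignant, TreatmentCategory.no_treatment,
                  Outcome.died_neoplasia, 1.0),
            _case(1, Malignancy.malignant, TreatmentCategory.surgery_only,
                  Outcome.died_neoplasia, 5.0),
            _case(2, Malignancy.benign, TreatmentCategory.surgery_only,
                  Outcome.alive, 10.0),
            _case(3, Malignancy.malignant, TreatmentCategory.no_treatment,
                  Outcome.died_other, 8.0),
            _case(4, Malignancy.malignant, TreatmentCategory.no_treatment,
                  Outcome.died_neoplasia, None),  # unknown survival: excluded
        ]
        grouped = survival.group_survival(Cohort(records))
        total = sum(int(c.n_events.sum() + c.n_censored.sum())
                    for c in grouped.curves.values())
        assert total == 4
        assert grouped.n_excluded_unknown_survival == 1

    def test_non_neoplastic_deaths_form_their_own_group(self):
        records = [
            _case(0, Malignancy.malignant, TreatmentCategory.surgery_only,
                  Outcome.died_other, 3.0),
            _case(1, Malignancy.malignant, TreatmentCategory.no_treatment,
                  Outcome.died_unknown_cause, 4.0),
        ]
        grouped = survival.group_survival(Cohort(records))
        assert list(grouped.curves) == [("malignant", "died_non_neoplastic")]
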