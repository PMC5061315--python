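import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvrisk.cohort import Cohort
from cvrisk.errors import DomainError
from cvrisk.evaluate import (
    calibration_deciles,
    evaluate_predictions,
    harrells_c,
    incidence_rate,
    observed_event_frequency,
    overestimation_pct,
    roc_export,
)

from conftest import make_cohort, make_subject


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the package implementations)
# ---------------------------------------------------------------------------


def brute_force_c(risks, times, events):
    """All-pairs double loop under the normative pair rules."""
    n = len(risks)
    usable = 0.0
    score = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if times[i] == times[j]:
                if events[i] and events[j]:
                    usable += 1
                    score += 0.5
                continue
            lo, hi = (i, j) if times[i] < times[j] else (j, i)
            if not events[lo]:
                continue
            usable += 1
            if risks[lo] > risks[hi]:
                score += 1.0
            elif risks[lo] == risks[hi]:
                score += 0.5
    return score / usable if usable else math.nan


def mann_whitney_auc(risks, labels):
    pos = [r for r, y in zip(risks, labels) if y]
    neg = [r for r, y in zip(risks, labels) if not y]
    u = 0.0
    for p in pos:
        for q in neg:
            u += 1.0 if p > q else (0.5 if p == q else 0.0)
    return u / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# frequencies and rates
# ---------------------------------------------------------------------------


class TestObservedEventFrequency:
    def test_printed_proportion_383_of_5238(self):
        cohort = make_cohort(5238, n_events=383, fu=8.6)
        f = observed_event_frequency(cohort, "ascvd", 10.0)
        assert f == pytest.approx(383 / 5238)
        assert round(100 * f, 1) == 7.3

    def test_printed_proportion_271_of_4208(self):
        cohort = make_cohort(4208, n_events=271, fu=9.0)
        f = observed_event_frequency(cohort, "ascvd", 10.0)
        assert round(100 * f, 1) == 6.4

    def test_zero_events(self):
        cohort = make_cohort(50)
        assert observed_event_frequency(cohort) == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(DomainError):
            observed_event_frequency(Cohort("e", []))

    def test_km_adjusts_for_censoring(self):
        # half censored at year 2, events at year 5 among the followed half
        subjects = []
        for i in range(100):
            if i < 50:
                subjects.append(make_subject(f"c{i}", fu_time_ascvd=2.0, event_ascvd=False))
            else:
                subjects.append(
                    make_subject(f"e{i}", fu_time_ascvd=5.0, event_ascvd=(i % 2 == 0))
                )
        cohort = Cohort("km", subjects)
        crude = observed_event_frequency(cohort, method="crude")
        km = observed_event_frequency(cohort, method="km")
        assert km > crude  # early censoring depresses the crude proportion


class TestIncidenceRate:
    def test_printed_rate(self):
        cohort = make_cohort(5238, n_events=383, fu=8.6)
        rate = incidence_rate(cohort)
        assert rate == pytest.approx(1000 * 383 / (5238 * 8.6), rel=1e-12)
        assert round(rate, 1) == 8.5

    def test_single_subject_no_event(self):
        cohort = Cohort("one", [make_subject("a", fu_time_ascvd=10.0, event_ascvd=False)])
        assert incidence_rate(cohort) == 0.0

    def test_direct_arithmetic(self):
        cohort = make_cohort(10, n_events=1, fu=10.0)
        assert incidence_rate(cohort) == pytest.approx(10.0)


class TestOverestimationPct:
    def test_paper_style_value(self):
        # estimated 10.0 vs observed 7.3 on unrounded scale
        assert overestimation_pct(10.0, 7.3) == pytest.approx((10 / 7.3 - 1) * 100)
        assert round(overestimation_pct(10.0, 7.3), 2) == 36.99

    def test_equal_rates_zero(self):
        assert overestimation_pct(4.2, 4.2) == 0.0

    def test_halving(self):
        assert overestimation_pct(5.0, 10.0) == -50.0

    def test_zero_observed_rejected(self):
        with pytest.raises(DomainError):
            overestimation_pct(5.0, 0.0)

    @given(a=st.floats(0.1, 50), b=st.floats(0.1, 50))
    @settings(max_examples=100)
    def test_sign_antisymmetric_around_equality(self, a, b):
        x = overestimation_pct(a, b)
        if a > b:
            assert x > 0
        elif a < b:
            assert x < 0
        else:
            assert x == 0


# ---------------------------------------------------------------------------
# decile calibration
# ---------------------------------------------------------------------------


class TestCalibrationDeciles:
    def test_ten_distinct_predictions_one_each(self):
        preds = np.linspace(0.05, 0.5, 10)
        table = calibration_deciles(preds, [False] * 10)
        assert list(table.table["n"]) == [1] * 10
        assert np.allclose(table.table["mean_pred"], sorted(preds))

    def test_constant_predictions_single_group_flagged(self):
        table = calibration_deciles([0.2] * 30, [True] * 10 + [False] * 20)
        assert len(table.table) == 1
        assert table.has_ties
        assert table.table["n"].iloc[0] == 30

    def test_group_sizes_differ_by_at_most_one_without_ties(self):
        rng = np.random.default_rng(1)
        preds = rng.uniform(0, 1, 1003)
        table = calibration_deciles(preds, rng.random(1003) < 0.2)
        sizes = table.table["n"]
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 1003

    def test_totals_row_matches_overall(self):
        rng = np.random.default_rng(2)
        preds = rng.uniform(0, 0.5, 200)
        events = rng.random(200) < preds
        table = calibration_deciles(preds, events)
        assert table.total_mean_pred == pytest.approx(preds.mean())
        assert table.total_observed == pytest.approx(events.mean())

    def test_too_few_subjects_refused(self):
        with pytest.raises(DomainError):
            calibration_deciles([0.1] * 9, [False] * 9)

    def test_deciles_ordered_by_mean_prediction(self):
        rng = np.random.default_rng(3)
        preds = rng.uniform(0, 1, 500)
        table = calibration_deciles(preds, rng.random(500) < 0.3)
        mp = list(table.table["mean_pred"])
        assert mp == sorted(mp)

    def test_calibrated_generator_recovers_diagonal(self):
        rng = np.random.default_rng(0)
        n = 50000
        preds = rng.beta(2, 12, n)
        events = rng.random(n) < preds
        table = calibration_deciles(preds, events)
        for _, row in table.table.iterrows():
            se = math.sqrt(row["mean_pred"] * (1 - row["mean_pred"]) / row["n"])
            assert abs(row["mean_pred"] - row["observed_freq"]) < 3.5 * se


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------


class TestHarrellsC:
    def test_perfect_ranking_no_censoring(self):
        # higher risk -> earlier event
        risks = [0.9, 0.7, 0.5, 0.3, 0.1]
        times = [1, 2, 3, 4, 5]
        events = [True] * 5
        assert harrells_c(risks, times, events, bootstrap=0).c == 1.0

    def test_null_predictions_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        risks = rng.uniform(0, 1, n)
        times = rng.exponential(5, n)
        events = rng.random(n) < 0.5
        c = harrells_c(risks, times, events, bootstrap=0).c
        assert abs(c - 0.5) < 0.02

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        # discretised times/risks to force plenty of ties
        times = rng.integers(1, 12, n).astype(float)
        events = rng.random(n) < 0.5
        risks = np.round(rng.uniform(0, 1, n), 1)
        expected = brute_force_c(list(risks), list(times), list(events))
        got = harrells_c(risks, times, events, bootstrap=0)
        assert got.c == pytest.approx(expected, abs=1e-12)

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(DomainError):
            harrells_c([0.1, 0.2], [5.0, 6.0], [False, False], bootstrap=0)

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        rng = np.random.default_rng(1)
        n = 150
        risks = rng.uniform(0, 1, n)
        times = rng.exponential(5, n)
        events = rng.random(n) < (risks * 0.8)
        a = harrells_c(risks, times, events, bootstrap=100, seed=7)
        b = harrells_c(risks, times, events, bootstrap=100, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low < a.c < a.ci_high

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(2)
        n = 300
        risks = rng.uniform(0.01, 0.9, n)
        times = rng.exponential(5, n)
        events = rng.random(n) < 0.3
        base = harrells_c(risks, times, events, bootstrap=0).c
        logit = np.log(risks / (1 - risks)) + 1.3
        affine = 0.2 * risks + 5.0
        assert harrells_c(logit, times, events, bootstrap=0).c == base
        assert harrells_c(affine, times, events, bootstrap=0).c == base

    def test_equals_auc_when_event_pairs_cannot_disagree(self):
        # C restricted to event-vs-censored pairs is the Mann-Whitney AUC;
        # event-event pairs (absent with a single event) are the only
        # difference between the two statistics
        rng = np.random.default_rng(3)
        n = 120
        risks = rng.uniform(0, 1, n)
        events = np.zeros(n, dtype=bool)
        events[17] = True
        times = np.where(events, 2.0, 9.0)
        c = harrells_c(risks, times, events, bootstrap=0).c
        _, auc = roc_export(risks, events)
        assert c == pytest.approx(mann_whitney_auc(list(risks), list(events)), abs=1e-12)
        assert c == pytest.approx(auc, abs=1e-12)

    def test_c_decomposes_into_auc_plus_event_pairs(self):
        # with all events preceding all censoring, usable pairs split into
        # event-vs-censored (AUC pairs) and event-vs-event (time-ranking) pairs
        rng = np.random.default_rng(3)
        n = 120
        risks = rng.uniform(0, 1, n)
        events = rng.random(n) < 0.4
        times = np.where(events, rng.uniform(1, 5, n), 9.0)
        c = harrells_c(risks, times, events, bootstrap=0).c
        n1 = int(events.sum())
        n0 = n - n1
        auc = mann_whitney_auc(list(risks), list(events))
        ee_score = 0.0
        idx = np.flatnonzero(events)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                lo, hi = (i, j) if times[i] < times[j] else (j, i)
                ee_score += 1.0 if risks[lo] > risks[hi] else (0.5 if risks[lo] == risks[hi] else 0.0)
        ee_pairs = n1 * (n1 - 1) / 2
        expected = (auc * n1 * n0 + ee_score) / (n1 * n0 + ee_pairs)
        assert c == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# ROC export
# ---------------------------------------------------------------------------


class TestRocExport:
    def test_perfect_separation(self):
        risks = [0.9, 0.8, 0.2, 0.1]
        labels = [True, True, False, False]
        _, auc = roc_export(risks, labels)
        assert auc == 1.0

    def test_identical_predictions_auc_half(self):
        _, auc = roc_export([0.3] * 10, [True] * 4 + [False] * 6)
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        risks = np.round(rng.uniform(0, 1, n), 1)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        _, auc = roc_export(risks, labels)
        assert auc == pytest.approx(mann_whitney_auc(list(risks), list(labels)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_export([0.1, 0.2], [True, True])

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(9)
        risks = rng.uniform(0, 1, 200)
        labels = rng.random(200) < 0.3
        df, _ = roc_export(risks, labels)
        assert (np.diff(df["fpr"]) >= 0).all()
        assert (np.diff(df["tpr"]) >= 0).all()


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


class TestEvaluationReport:
    def test_internal_consistency(self):
        cohort = make_cohort(200, n_events=30, seed=5)
        rng = np.random.default_rng(0)
        preds = rng.uniform(0.01, 0.4, 200)
        report = evaluate_predictions(cohort, preds, "dummy", bootstrap=20, seed=0)
        expected = overestimation_pct(report.mean_estimated, report.observed_freq)
        assert report.overestimation == pytest.approx(expected, abs=1e-12)
        assert report.n == 200
        assert report.n_events == 30
        assert report.calibration is not None
        assert report.calibration.n == 200

    def test_rounded_row_mirrors_full_precision(self):
        cohort = make_cohort(100, n_events=20, seed=6)
        rng = np.random.default_rng(1)
        preds = rng.uniform(0.05, 0.3, 100)
        row = evaluate_predictions(cohort, preds, "dummy", bootstrap=0).to_row()
        assert row["observed_freq_pct"] == round(row["observed_freq_pct_full"], 1)
        assert row["overestimation_pct"] == round(row["overestimation_pct_full"], 1)
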