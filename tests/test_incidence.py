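"""Kaplan-Meier incidence, curve comparison statistics, and the OLS decomposition."""

import numpy as np
import pytest

from ademiner.corpus import DocType
from ademiner.incidence import (
    IncidenceCurve,
    curve_correlation,
    detection_gap,
    detection_ratio,
    km_incidence,
    per_doctype_curves,
    regress_all_on_per_doc,
)
from ademiner.timeline import PatientTimeline, TimelineEvent

import datetime

FIRST = datetime.date(2020, 3, 10)


def timeline(pid, event_days_types, followup):
    return PatientTimeline(
        patient_id=pid, first_dose_date=FIRST,
        events=tuple(TimelineEvent(d, dt, "末梢神経障害") for d, dt in event_days_types),
        followup_end_day=followup,
    )


class TestKmIncidence:
    def test_no_censoring_closed_form(self):
        curve = km_incidence([5, 5], [10, 10], horizon=8)
        assert np.all(curve.incidence[:5] == 0.0)
        assert np.all(curve.incidence[5:] == 1.0)

    def test_hand_computed_product_limit(self):
        # onsets {2,4}, censored {3,6}: S(2)=3/4, S(4)=3/4 * 1/2 = 3/8
        curve = km_incidence([2, 4, None, None], [10, 10, 3, 6], horizon=6)
        assert curve.at(1) == pytest.approx(0.0)
        assert curve.at(2) == pytest.approx(0.25)
        assert curve.at(3) == pytest.approx(0.25)
        assert curve.at(4) == pytest.approx(0.625)
        assert curve.at(6) == pytest.approx(0.625)

    def test_all_censored_identically_zero(self):
        curve = km_incidence([None] * 4, [3, 6, 9, 12], horizon=12)
        assert np.all(curve.incidence == 0.0)

    def test_no_censoring_equals_empirical_cdf_random_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(1, 51))
            onsets = rng.integers(0, 40, size=n).tolist()
            curve = km_incidence(onsets, [60] * n, horizon=50)
            for t in range(51):
                ecdf = sum(o <= t for o in onsets) / n
                assert curve.at(t) == pytest.approx(ecdf), t

    def test_curve_invariants(self):
        rng = np.random.default_rng(1)
        onsets = [int(o) if rng.random() < 0.6 else None for o in rng.integers(0, 30, 40)]
        censors = [int(c) for c in rng.integers(30, 60, 40)]
        curve = km_incidence(onsets, censors, horizon=59)
        assert np.all(np.diff(curve.incidence) >= -1e-12)
        assert np.all(curve.ci_lower <= curve.incidence + 1e-9)
        assert np.all(curve.incidence <= curve.ci_upper + 1e-9)
        assert np.all(curve.ci_lower >= -1e-9) and np.all(curve.ci_upper <= 1 + 1e-9)
        assert np.all(np.diff(curve.n_at_risk) <= 0)

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="empty"):
            km_incidence([], [], horizon=10)
        with pytest.raises(ValueError, match="onset day 7 after censor"):
            km_incidence([7], [5], horizon=10)


class TestPerDoctypeCurves:
    def _timelines(self):
        return [
            timeline("a", [(5, DocType.pharmacist_note)], 60),
            timeline("b", [(10, DocType.physician_note), (20, DocType.pharmacist_note)], 60),
            timeline("c", [], 60),
        ]

    def test_event_only_in_its_own_doc_type_curve(self):
        curves = per_doctype_curves(self._timelines(), horizon=60)
        assert curves["pharmacist_note"].at(5) > 0
        assert curves["radiology_report"].at(60) == 0.0

    def test_all_curve_dominates_every_single_type(self):
        curves = per_doctype_curves(self._timelines(), horizon=60)
        for dt in DocType:
            assert np.all(curves["all"].incidence >= curves[dt.value].incidence - 1e-12)

    def test_zero_mention_type_is_flat_zero(self):
        curves = per_doctype_curves(self._timelines(), horizon=60)
        assert np.all(curves["discharge_summary"].incidence == 0.0)

    def test_unknown_doc_type_rejected(self):
        with pytest.raises(ValueError):
            per_doctype_curves(self._timelines(), doc_types=["lab_result"], horizon=60)


class TestDetectionGapAndRatio:
    def test_worked_gap(self):
        assert detection_gap(74.0, 60.7) == pytest.approx(13.3)

    def test_gap_zero_and_sign_convention(self):
        assert detection_gap(55.0, 55.0) == 0.0
        assert detection_gap(50.0, 60.0) == pytest.approx(-10.0)

    def test_gap_plus_system_is_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            r, s = rng.uniform(0, 100, 2)
            assert detection_gap(r, s) + s == pytest.approx(r)

    def test_worked_ratio(self):
        system = IncidenceCurve.from_series(range(31), [0.0] * 30 + [0.607])
        reference = IncidenceCurve.from_series(range(31), [0.0] * 30 + [0.740])
        assert detection_ratio(system, reference, 30) == pytest.approx(0.820, abs=5e-4)

    def test_identical_curves_ratio_one(self):
        c = IncidenceCurve.from_series(range(11), np.linspace(0.1, 0.9, 11))
        for day in range(11):
            assert detection_ratio(c, c, day) == pytest.approx(1.0)

    def test_zero_reference_is_error(self):
        zero = IncidenceCurve.from_series(range(5), [0.0] * 5)
        with pytest.raises(ZeroDivisionError):
            detection_ratio(zero, zero, 2)


class TestCurveCorrelation:
    def test_identical_curves(self):
        c = IncidenceCurve.from_series(range(20), np.linspace(0, 0.8, 20))
        r, p = curve_correlation(c, c, 19)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self):
        base = np.linspace(0, 0.6, 30)
        a = IncidenceCurve.from_series(range(30), base)
        b = IncidenceCurve.from_series(range(30), 0.5 * base + 0.1)
        r, _ = curve_correlation(a, b, 29)
        assert r == pytest.approx(1.0)

    def test_staircase_series_direct_formula_oracle(self):
        xs = np.array([0.0, 0.0, 0.1, 0.1, 0.3, 0.3, 0.3, 0.6, 0.6, 0.7])
        ys = np.array([0.0, 0.1, 0.1, 0.2, 0.2, 0.5, 0.5, 0.5, 0.8, 0.8])
        a = IncidenceCurve.from_series(range(10), xs)
        b = IncidenceCurve.from_series(range(10), ys)
        r, _ = curve_correlation(a, b, 9)
        # direct Pearson formula as an independent oracle
        expected = (np.mean(xs * ys) - xs.mean() * ys.mean()) / (xs.std() * ys.std())
        assert r == pytest.approx(expected)

    def test_constant_series_is_error(self):
        flat = IncidenceCurve.from_series(range(10), [0.2] * 10)
        ramp = IncidenceCurve.from_series(range(10), np.linspace(0, 1, 10))
        with pytest.raises(ValueError, match="constant"):
            curve_correlation(flat, ramp, 9)


class TestRegression:
    def _curves(self):
        days = range(40)
        rng = np.random.default_rng(3)
        a = np.sort(rng.uniform(0, 0.5, 40))
        b = np.sort(rng.uniform(0, 0.4, 40))
        return days, a, b

    def test_exact_single_curve_recovery(self):
        days, a, b = self._curves()
        all_curve = IncidenceCurve.from_series(days, a)
        fit = regress_all_on_per_doc(
            all_curve,
            {"x": IncidenceCurve.from_series(days, a),
             "y": IncidenceCurve.from_series(days, b)},
            39,
        )
        assert fit.coefficients["x"] == pytest.approx(1.0, abs=1e-8)
        assert fit.coefficients["y"] == pytest.approx(0.0, abs=1e-8)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_half_half_combination_vs_normal_equations(self):
        days, a, b = self._curves()
        y = 0.5 * a + 0.5 * b
        fit = regress_all_on_per_doc(
            IncidenceCurve.from_series(days, y),
            {"x": IncidenceCurve.from_series(days, a),
             "y": IncidenceCurve.from_series(days, b)},
            39,
        )
        # independent normal-equations solve
        X = np.column_stack([np.ones(40), a, b])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.coefficients["x"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.coefficients["y"] == pytest.approx(beta[2], abs=1e-8)
        assert all(se >= 0 for se in fit.std_errors.values())

    def test_constant_predictor_dropped_fit_unchanged(self):
        days, a, b = self._curves()
        y = 0.3 * a
        with_zero = regress_all_on_per_doc(
            IncidenceCurve.from_series(days, y),
            {"x": IncidenceCurve.from_series(days, a),
             "flat": IncidenceCurve.from_series(days, [0.0] * 40)},
            39,
        )
        without = regress_all_on_per_doc(
            IncidenceCurve.from_series(days, y),
            {"x": IncidenceCurve.from_series(days, a)},
            39,
        )
        assert with_zero.dropped == ("flat",)
        assert with_zero.coefficients["x"] == pytest.approx(without.coefficients["x"])

    def test_too_few_observations_is_error(self):
        days, a, b = self._curves()
        with pytest.raises(ValueError):
            regress_all_on_per_doc(
                IncidenceCurve.from_series(days, a),
                {"x": IncidenceCurve.from_series(days, a),
                 "y": IncidenceCurve.from_series(days, b)},
                2,
            )
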