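"""Derivative vectors, wedge areas, threshold calibration, prediction."""

import numpy as np
import pytest

from tempomine.errors import (
    ConfigurationError,
    InsufficientDataError,
    UndefinedInputError,
)
from tempomine.records import PatientSeries, TemporalObservation, denormalize_panel
from tempomine.sn import (
    SELECTED_PARAMETERS,
    calibrate_threshold,
    derivative_at,
    differential_area,
    labelled_pairs,
    predict_series,
    predict_state,
    wedge_area,
)


def series_from_normalized(normalized_rows, ranges, times=None, states=None,
                           pid="P1"):
    """Build a PatientSeries from rows of normalized (c, b, s, g) values."""
    times = times if times is not None else [float(i) for i in range(len(normalized_rows))]
    observations = []
    for k, row in enumerate(normalized_rows, start=1):
        panel = denormalize_panel(dict(zip(SELECTED_PARAMETERS, row)), ranges)
        state = states[k - 1] if states else None
        observations.append(
            TemporalObservation(pid, k, times[k - 1], panel, state))
    return PatientSeries(pid, observations)


class TestDerivative:
    def test_baseline_at_midpoints_is_zero_vector(self, ranges):
        series = series_from_normalized([[0, 0, 0, 0], [1, 1, 1, 1]], ranges)
        j1 = derivative_at(series, 1, ranges)
        assert np.allclose(j1.components, 0)
        assert j1.dt == 1.0

    def test_baseline_is_normalized_deviation(self, ranges):
        series = series_from_normalized([[0.5, -0.25, 1.0, 2.0], [0, 0, 0, 0]], ranges)
        j1 = derivative_at(series, 1, ranges)
        assert np.allclose(j1.components, [0.5, -0.25, 1.0, 2.0])

    def test_constant_panel_gives_zero_derivative(self, ranges):
        series = series_from_normalized([[0.3] * 4, [0.3] * 4], ranges)
        assert np.allclose(derivative_at(series, 2, ranges).components, 0)

    def test_hand_computed_rate(self, ranges):
        # normalized creatinine 0.5 -> 1.1 over 30 days: rate 0.02 / day
        series = series_from_normalized(
            [[0.5, 0, 0, 0], [1.1, 0, 0, 0]], ranges, times=[0.0, 30.0])
        j2 = derivative_at(series, 2, ranges)
        assert j2.components[0] == pytest.approx(0.02)
        assert j2.dt == pytest.approx(30.0)

    def test_unknown_point_raises(self, ranges):
        series = series_from_normalized([[0] * 4, [1] * 4], ranges)
        with pytest.raises(IndexError):
            derivative_at(series, 9, ranges)

    def test_missing_selected_parameter_is_unusable(self, ranges):
        obs = [
            TemporalObservation("P1", 1, 0.0, {"creatinine": 0.9, "bun": 14.0}),
        ]
        series = PatientSeries("P1", obs)
        with pytest.raises(UndefinedInputError, match="sgot"):
            derivative_at(series, 1, ranges)


class TestWedgeArea:
    def test_unit_square(self):
        assert wedge_area(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_collinear_is_zero(self, rng):
        for p in (2, 3, 4):
            dx = rng.normal(size=p)
            assert wedge_area(dx, 3.0 * dx) == pytest.approx(0.0, abs=1e-9)

    def test_p2_equals_absolute_determinant(self, rng):
        for _ in range(1000):
            dx, dy = rng.normal(size=2), rng.normal(size=2)
            det = abs(dx[0] * dy[1] - dx[1] * dy[0])
            assert wedge_area(dx, dy) == pytest.approx(det, rel=1e-12, abs=1e-300)

    def test_p4_equals_gram_determinant_oracle(self, rng):
        for _ in range(1000):
            dx, dy = rng.normal(size=4), rng.normal(size=4)
            gram = np.array([[dx @ dx, dx @ dy], [dx @ dy, dy @ dy]])
            oracle = np.sqrt(max(np.linalg.det(gram), 0.0))
            assert wedge_area(dx, dy) == pytest.approx(oracle, rel=1e-9)

    def test_symmetry_and_sign_invariance(self, rng):
        dx, dy = rng.normal(size=4), rng.normal(size=4)
        a = wedge_area(dx, dy)
        assert wedge_area(dy, dx) == pytest.approx(a)
        assert wedge_area(-dx, -dy) == pytest.approx(a)

    def test_dimension_errors(self):
        with pytest.raises(ValueError):
            wedge_area(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            wedge_area(np.array([1.0]), np.array([2.0]))


class TestDifferentialArea:
    def test_consistent_trend_gives_zero(self, ranges):
        # baseline deviation and both increments all along the same direction
        d = np.array([0.5, 0.25, 0.1, 0.05])
        series = series_from_normalized([d, 2 * d, 3 * d], ranges)
        assert differential_area(series, 2, ranges).dA == pytest.approx(0.0, abs=1e-12)
        assert differential_area(series, 3, ranges).dA == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_jump_two_parameter_case(self, ranges):
        # move 0.4 in c then 0.3 in b: parallelogram area 0.4 * 0.3
        rows = [[0.0, 0.0], [0.4, 0.0], [0.4, 0.3]]
        rows = [r + [0.0, 0.0] for r in rows]
        series = series_from_normalized(rows, ranges)
        area = differential_area(series, 3, ranges)
        assert area.dA == pytest.approx(0.4 * 0.3)

    def test_invariant_under_visit_spacing(self, ranges):
        rows = [[0.1, 0.2, 0.0, 0.0], [0.5, 0.1, 0.0, 0.0], [0.3, 0.9, 0.2, 0.0]]
        narrow = series_from_normalized(rows, ranges, times=[0, 30, 60])
        wide = series_from_normalized(rows, ranges, times=[0, 60, 120])
        assert differential_area(narrow, 3, ranges).dA == pytest.approx(
            differential_area(wide, 3, ranges).dA)

    def test_baseline_point_has_no_pair(self, ranges):
        series = series_from_normalized([[0] * 4, [1] * 4], ranges)
        with pytest.raises(IndexError):
            differential_area(series, 1, ranges)


class TestPredictState:
    def test_zero_area_persists(self):
        assert predict_state(1, 0.0, 0.5).predicted_state == 1

    def test_area_above_threshold_progresses(self):
        assert predict_state(1, 0.6, 0.5).predicted_state == 2

    def test_huge_threshold_always_persists(self):
        assert predict_state(3, 1e9, 1e12).predicted_state == 3

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            predict_state(1, 0.1, -0.5)


class TestCalibration:
    def test_separable_midpoint(self):
        theta = calibrate_threshold([(0.1, True), (0.2, True), (0.8, False)])
        assert theta == pytest.approx(0.5)

    def test_all_persisting_uses_max(self):
        assert calibrate_threshold([(0.1, True), (0.4, True)]) == pytest.approx(0.4)

    def test_all_progressing_uses_half_minimum(self):
        assert calibrate_threshold([(0.6, False), (0.9, False)]) == pytest.approx(0.3)

    def test_empty_rejected(self):
        with pytest.raises(UndefinedInputError):
            calibrate_threshold([])

    def test_non_separable_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            pairs = [(float(d), bool(p)) for d, p in zip(
                rng.uniform(0, 1, size=12), rng.random(12) < 0.5)]
            theta = calibrate_threshold(pairs)
            # oracle: scan every candidate cut, min error, smallest theta
            cands = sorted({0.0, *(d for d, _ in pairs)})
            errs = {c: sum((d <= c) != p for d, p in pairs) for c in cands}
            best = min(errs.values())
            err_at_theta = sum((d <= theta) != p for d, p in pairs)
            assert err_at_theta == best

    def test_progression_calls_shrink_as_theta_grows(self, rng):
        areas = rng.uniform(0, 1, size=100)
        prev_calls = None
        for theta in (0.1, 0.3, 0.5, 0.9):
            calls = {i for i, a in enumerate(areas) if a > theta}
            if prev_calls is not None:
                assert calls <= prev_calls
            prev_calls = calls


class TestPredictSeries:
    def test_flat_series_persists_at_anchor(self, ranges):
        d = np.array([0.2, 0.1, 0.3, 0.4])
        series = series_from_normalized([d, 2 * d, 3 * d], ranges)
        preds = predict_series(series, 0.05, ranges, anchor=1)
        assert [p.predicted_state for p in preds] == [1, 1]
        assert [p.point_index for p in preds] == [2, 3]

    def test_two_point_series_single_prediction(self, ranges):
        series = series_from_normalized([[0.1] * 4, [0.2] * 4], ranges)
        preds = predict_series(series, 0.5, ranges, anchor=1)
        assert len(preds) == 1 and preds[0].point_index == 2

    def test_short_series_rejected(self, ranges):
        series = series_from_normalized([[0.1] * 4], ranges)
        with pytest.raises(InsufficientDataError):
            predict_series(series, 0.5, ranges, anchor=1)

    def test_missing_anchor_rejected(self, ranges):
        series = series_from_normalized([[0.1] * 4, [0.2] * 4], ranges)
        with pytest.raises(InsufficientDataError):
            predict_series(series, 0.5, ranges)

    def test_chained_progression(self, ranges):
        # direction break at point 3 with a tiny threshold: progress once
        rows = [[0.1, 0.0, 0.0, 0.0], [0.2, 0.0, 0.0, 0.0], [0.2, 0.5, 0.0, 0.0]]
        series = series_from_normalized(rows, ranges)
        preds = predict_series(series, 1e-6, ranges, anchor=1)
        assert [p.predicted_state for p in preds] == [1, 2]

    def test_causality_prefix_property(self, ranges, rng):
        """Truncating the series never changes earlier predictions."""
        for _ in range(20):
            rows = rng.normal(scale=0.5, size=(5, 4))
            series = series_from_normalized(rows, ranges)
            full = predict_series(series, 0.2, ranges, anchor=1)
            for cut in range(2, 5):
                truncated = PatientSeries("P1", series.observations[:cut])
                partial = predict_series(truncated, 0.2, ranges, anchor=1)
                assert [(p.point_index, p.predicted_state) for p in partial] == [
                    (p.point_index, p.predicted_state) for p in full[: cut - 1]]

    def test_evaluation_mode_anchors_on_observed_states(self, ranges):
        rows = [[0.1, 0, 0, 0], [0.2, 0, 0, 0], [0.2, 0.5, 0, 0]]
        series = series_from_normalized(rows, ranges, states=[1, 5, 5])
        preds = predict_series(series, 1e9, ranges, evaluation_mode=True)
        # point-3 prediction anchors on observed state 5 at point 2
        assert preds[1].anchor_state == 5
        assert preds[1].predicted_state == 5

    def test_labelled_pairs_extraction(self, ranges):
        rows = [[0.1, 0, 0, 0], [0.2, 0, 0, 0], [0.2, 0.5, 0, 0]]
        series = series_from_normalized(rows, ranges, states=[1, 1, 2])
        pairs = labelled_pairs([series], ranges)
        assert len(pairs) == 2
        assert pairs[0][1] is True and pairs[1][1] is False
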