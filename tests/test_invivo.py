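"""Tumor volumetrics, trial logic, KM curves and the log-rank test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combiscreen import (
    TumorMeasurement,
    TumorTrack,
    detect_relapse,
    endpoint_check,
    km_curve,
    logrank_test,
    treatment_trigger,
    tumor_response,
    tumor_volume,
)
from combiscreen.errors import (
    DomainError,
    InsufficientDataError,
    UndefinedTestError,
)


def cube_track(volumes, subject="m1", arm="combination", start_day=0, step=7):
    """Track with equal-axis measurements realizing the given volumes."""
    track = TumorTrack(subject_id=subject, arm=arm)
    for i, v in enumerate(volumes):
        axis = (2.0 * v) ** (1.0 / 3.0)
        track.measurements.append(
            TumorMeasurement(subject, start_day + i * step, axis, axis, axis)
        )
    return track


class TestTumorVolume:
    def test_hand_value(self):
        assert tumor_volume(10, 10, 10) == 500.0

    def test_zero_axis(self):
        assert tumor_volume(0, 5, 7) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0, 30), b=st.floats(0, 30), c=st.floats(0, 30),
        s=st.floats(0.1, 10),
    )
    def test_symmetry_and_cubic_scaling(self, a, b, c, s):
        v = tumor_volume(a, b, c)
        assert tumor_volume(c, a, b) == pytest.approx(v, rel=1e-12)
        assert tumor_volume(b, c, a) == pytest.approx(v, rel=1e-12)
        assert tumor_volume(s * a, s * b, s * c) == pytest.approx(s**3 * v, rel=1e-9)

    def test_negative_axis_rejected(self):
        with pytest.raises(DomainError):
            tumor_volume(-1, 2, 3)


class TestTrialThresholds:
    @pytest.mark.parametrize(
        "axes, expected",
        [((5.0, 3, 2), True), ((4.9, 4.9, 4.9), False), ((2, 6, 1), True)],
    )
    def test_treatment_trigger_max_axis(self, axes, expected):
        m = TumorMeasurement("m", 0, *axes)
        assert treatment_trigger(m) is expected

    @pytest.mark.parametrize(
        "axes, expected",
        [((15, 4, 4), True), ((14.9, 14.9, 14.9), False), ((1, 1, 16), True)],
    )
    def test_endpoint_max_axis(self, axes, expected):
        m = TumorMeasurement("m", 0, *axes)
        assert endpoint_check(m) is expected


class TestTumorResponse:
    def test_zero_at_baseline(self):
        track = cube_track([100, 200, 400])
        assert tumor_response(track, 0) == pytest.approx(0.0, abs=1e-9)

    def test_15_fold_growth_is_plus_1400(self):
        track = cube_track([100.0, 1500.0], step=14)
        assert tumor_response(track, 14) == pytest.approx(1400.0, rel=1e-9)

    def test_eradication_is_minus_100(self):
        track = cube_track([100.0, 0.0], step=7)
        assert tumor_response(track, 7) == pytest.approx(-100.0)

    def test_nearest_day_within_tolerance(self):
        track = cube_track([100.0, 300.0], step=7)
        assert tumor_response(track, 8) == tumor_response(track, 7)
        with pytest.raises(InsufficientDataError):
            tumor_response(track, 20)

    def test_unit_invariance(self):
        # same shape expressed in different length units: same response %
        t_mm = cube_track([100.0, 800.0], step=7)
        t_scaled = TumorTrack(subject_id="m2", arm="vehicle")
        for m in t_mm.measurements:
            t_scaled.measurements.append(
                TumorMeasurement("m2", m.day, 2 * m.width, 2 * m.depth, 2 * m.height)
            )
        assert tumor_response(t_scaled, 7) == pytest.approx(
            tumor_response(t_mm, 7), rel=1e-9
        )

    def test_baseline_requires_trigger(self):
        track = cube_track([10.0, 20.0])  # axes stay below 5 mm
        with pytest.raises(InsufficientDataError):
            tumor_response(track, 0)


class TestDetectRelapse:
    def test_rebound_after_regression(self):
        track = cube_track([100, 0, 0, 80])
        assert detect_relapse(track) == [21]  # 4th scan, weekly cadence

    def test_monotone_growth_no_relapse(self):
        assert detect_relapse(cube_track([100, 200, 400, 800])) == []

    def test_sustained_regression_no_relapse(self):
        assert detect_relapse(cube_track([100, 0, 0, 0])) == []

    def test_two_regression_rebound_cycles(self):
        track = cube_track([100, 0, 80, 0, 0, 90])
        assert detect_relapse(track) == [14, 35]

    def test_small_rebound_below_threshold_ignored(self):
        track = cube_track([100, 0, 5.0, 0])  # rebound below 10 mm3
        assert detect_relapse(track) == []

    def test_needs_two_measurements(self):
        with pytest.raises(InsufficientDataError):
            detect_relapse(cube_track([100]))


# --- survival ---------------------------------------------------------------


def hand_logrank(group_a, group_b):
    """Independent two-group Mantel-Cox chi-square, computed from first
    principles (risk tables at each distinct event time)."""
    data = [(t, s != "censored", 0) for t, s in group_a]
    data += [(t, s != "censored", 1) for t, s in group_b]
    event_times = sorted({t for t, obs, _ in data if obs})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = [(g, obs) for tt, obs, g in data if tt >= t]
        n = len(at_risk)
        n1 = sum(1 for g, _ in at_risk if g == 0)
        d = sum(1 for tt, obs, _ in data if obs and tt == t)
        d1 = sum(1 for tt, obs, g in data if obs and tt == t and g == 0)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        events = [(10, "death"), (20, "euthanized")]
        curve = km_curve(events)
        assert curve.times == [0.0, 10.0, 20.0]
        assert curve.survival == pytest.approx([1.0, 0.5, 0.0])

    def test_all_censored_flat_at_one(self):
        curve = km_curve([(30, "censored")] * 4)
        assert all(s == 1.0 for s in curve.survival)

    def test_six_subject_product_limit_hand_table(self):
        # hand-computed product-limit: deaths at 3, 6, 10 interleaved with
        # censorings at 4, 8, 12 -> S = 5/6, 5/8, 5/16 at the drop times
        events = [
            (3, "death"), (4, "censored"), (6, "death"),
            (8, "censored"), (10, "death"), (12, "censored"),
        ]
        curve = km_curve(events)
        table = dict(zip(curve.times, curve.survival))
        assert table[3.0] == pytest.approx(5 / 6)
        assert table[6.0] == pytest.approx(5 / 6 * 3 / 4)
        assert table[10.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)

    def test_monotone_and_starts_at_one(self):
        rng = np.random.default_rng(5)
        events = [
            (int(d), "death" if rng.random() < 0.7 else "censored")
            for d in rng.integers(1, 60, 25)
        ]
        curve = km_curve(events)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_km_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(8)
        days = sorted(rng.integers(1, 40, 12))
        curve = km_curve([(d, "death") for d in days])
        days_arr = np.asarray(days, dtype=float)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(days_arr > t), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            km_curve([])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = [(10, "death"), (20, "death"), (30, "censored")]
        stat, p = logrank_test([g, list(g)])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_fully_separated_groups_reject(self):
        a = [(d, "death") for d in (1, 2, 3, 4, 5)]
        b = [(d, "death") for d in (11, 12, 13, 14, 15)]
        stat, p = logrank_test([a, b])
        assert p < 0.01

    def test_matches_hand_mantel_cox(self):
        a = [(3, "death"), (7, "censored"), (11, "death"), (14, "death")]
        b = [(5, "death"), (9, "death"), (16, "censored"), (21, "death")]
        stat, _ = logrank_test([a, b])
        assert stat == pytest.approx(hand_logrank(a, b), rel=1e-9)

    def test_matches_exhaustive_permutation_reference(self):
        # n=8, all 70 balanced label assignments: the permutation p-value of
        # the Mantel-Cox statistic must agree with the chi-square p within
        # the resolution of a 70-point permutation distribution
        days = [2, 4, 6, 9, 12, 15, 19, 25]
        status = ["death"] * 6 + ["censored", "death"]
        events = list(zip(days, status))
        obs_a = [0, 1, 2, 3]
        stat_obs, p_chi2 = logrank_test(
            [[events[i] for i in obs_a], [events[i] for i in range(8) if i not in obs_a]]
        )
        perm_stats = []
        for idx_a in itertools.combinations(range(8), 4):
            a = [events[i] for i in idx_a]
            b = [events[i] for i in range(8) if i not in idx_a]
            perm_stats.append(hand_logrank(a, b))
        p_perm = np.mean(np.asarray(perm_stats) >= stat_obs - 1e-12)
        assert abs(p_perm - p_chi2) < 0.15
        # and the observed statistic itself matches the oracle's computation
        assert stat_obs == pytest.approx(hand_logrank(
            [events[i] for i in obs_a],
            [events[i] for i in range(8) if i not in obs_a],
        ), rel=1e-9)

    def test_three_groups_has_two_df(self):
        rng = np.random.default_rng(3)
        groups = [
            [(int(d), "death") for d in rng.integers(low, low + 20, 6)]
            for low in (1, 5, 30)
        ]
        stat, p = logrank_test(groups)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(stat, df=2), rel=1e-9)

    def test_no_events_undefined(self):
        g = [(10, "censored")] * 3
        with pytest.raises(UndefinedTestError):
            logrank_test([g, list(g)])

    def test_single_group_rejected(self):
        with pytest.raises(UndefinedTestError):
            logrank_test([[(10, "death")]])
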