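"""RSD statistics, steady-state/failure rules and the screening pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adwarn import indicators as ind
from adwarn import synthetic
from adwarn.indicators import (
    EXPERIMENTAL_THRESHOLDS,
    SteadyStatePeriod,
    amplitude_range,
    detect_abrupt_change,
    detect_failure,
    detect_steady_periods,
    rsd_pair,
    screen,
    warning_time,
)


def _series(values, start_day=0):
    days = np.arange(start_day, start_day + len(values))
    return pd.Series(np.asarray(values, dtype=float), index=pd.Index(days, name="day"))


class TestRsdPair:
    def test_equal_days_zero(self):
        assert rsd_pair(1.0, 1.0) == 0.0

    def test_worked_value(self):
        # |1.2 - 1.0| / (sqrt(2) * 1.1) * 100
        assert rsd_pair(1.2, 1.0) == pytest.approx(12.856, abs=5e-4)

    def test_scale_invariance(self):
        assert rsd_pair(2.4, 2.0) == pytest.approx(rsd_pair(1.2, 1.0), rel=1e-12)

    def test_zero_mean_is_missing(self):
        assert math.isnan(rsd_pair(1.0, -1.0))

    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4))
    @settings(max_examples=100, derandomize=True)
    def test_matches_closed_form(self, a, b):
        xbar = (a + b) / 2
        want = abs(a - b) / (math.sqrt(2.0) * xbar) * 100.0
        assert rsd_pair(a, b) == pytest.approx(want, abs=1e-12, rel=1e-12)


class TestSteadyPeriods:
    def test_constant_series_is_one_period(self):
        periods = detect_steady_periods(_series([5.0] * 10))
        assert len(periods) == 1
        assert (periods[0].start_day, periods[0].end_day) == (0, 9)

    def test_alternating_20pct_never_steady(self):
        vals = [1.2 if i % 2 else 0.8 for i in range(20)]
        assert detect_steady_periods(_series(vals)) == []

    def test_embedded_flat_segment_recovered(self):
        swing = lambda n: 1.0 + 0.25 * np.array([1 if i % 2 else -1 for i in range(n)])  # noqa: E731
        vals = np.concatenate([swing(10), np.full(8, 3.0), swing(10)])
        periods = detect_steady_periods(_series(vals))
        assert [(p.start_day, p.end_day) for p in periods] == [(10, 17)]

    def test_minimum_length_respected(self):
        vals = [1.2, 0.8] * 3 + [1.0] * 5 + [1.4, 0.7] * 3
        assert detect_steady_periods(_series(vals)) == []


class TestFailureRule:
    def test_ph_crossing_is_failure_day(self):
        ph = _series([6.8] * 112 + [6.3] + [6.2] * 5)
        assert detect_failure(ph) == 112

    def test_stable_reactor_never_fails(self):
        ph = _series([6.8] * 50)
        ch4 = _series([0.2] * 50)
        assert detect_failure(ph, ch4) is None

    def test_yield_drop_is_failure(self):
        ph = _series([6.8] * 50)
        ch4 = _series([0.2] * 30 + [0.1] * 20)  # -50% step: RSD 47%
        assert detect_failure(ph, ch4) == 30

    def test_yield_rise_is_not_failure(self):
        ph = _series([6.8] * 50)
        ch4 = _series([0.2] * 30 + [0.3] * 20)
        assert detect_failure(ph, ch4) is None


class TestAbruptChange:
    def test_constant_series_no_event(self):
        assert detect_abrupt_change(_series([1.0] * 30), (5, 25), +1) is None

    def test_step_in_direction_detected(self):
        vals = [1.0] * 15 + [1.5] * 15  # +50%: RSD 28.3%
        event = detect_abrupt_change(_series(vals), (5, 25), +1)
        assert event is not None and event.day == 15
        assert event.rsd == pytest.approx(100 * 0.5 / (math.sqrt(2) * 1.25), rel=1e-9)

    def test_step_against_direction_ignored(self):
        vals = [1.0] * 15 + [1.5] * 15
        assert detect_abrupt_change(_series(vals), (5, 25), -1) is None

    def test_slight_days_reported(self):
        vals = [1.0] * 10 + [1.2] * 10 + [1.9] * 10  # +20% (12.9%), then +58% (25%)
        event = detect_abrupt_change(_series(vals), (0, 29), +1)
        assert event.day == 20
        assert event.slight_days == (10,)


class TestWarningTime:
    @pytest.mark.parametrize("abrupt, failure, want", [(105, 112, 7), (147, 159, 12), (10, 10, 0)])
    def test_day_difference(self, abrupt, failure, want):
        days, late = warning_time(abrupt, failure)
        assert (days, late) == (want, False)

    def test_abrupt_after_failure_flags(self):
        assert warning_time(161, 160) == (0, True)


class TestAmplitudeRange:
    def _periods(self, extremes):
        return [SteadyStatePeriod(i, i + 9, mean=e, minimum=e, maximum=e) for i, e in enumerate(extremes)]

    def test_published_worked_example(self):
        lo, hi = amplitude_range(0.98, self._periods([0.20, 0.23, 0.22, 0.20, 0.19]), +1)
        assert lo == pytest.approx(326.087, abs=0.05)
        assert hi == pytest.approx(415.789, abs=0.05)

    def test_single_extreme(self):
        lo, hi = amplitude_range(0.98, self._periods([0.20]), +1)
        assert lo == hi == pytest.approx(390.0, abs=1e-9)

    def test_reference_equal_extreme_is_zero(self):
        lo, hi = amplitude_range(0.5, self._periods([0.5]), +1)
        assert lo == hi == 0.0

    def test_falling_indicator_uses_minimum(self):
        periods = [
            SteadyStatePeriod(0, 9, mean=1.5, minimum=1.2, maximum=1.8),
            SteadyStatePeriod(20, 29, mean=1.6, minimum=1.4, maximum=1.9),
        ]
        lo, hi = amplitude_range(0.9, periods, -1)
        assert lo == pytest.approx((0.9 - 1.4) / 1.4 * 100.0)
        assert hi == pytest.approx((0.9 - 1.2) / 1.2 * 100.0)

    def test_identical_bounds_fall_back_to_period_means(self):
        # when every period shows the same change, the comparison is redone
        # against the period averages (single standalone value)
        periods = [SteadyStatePeriod(0, 9, mean=1.5, minimum=1.2, maximum=1.8)]
        lo, hi = amplitude_range(0.9, periods, -1)
        assert lo == hi == pytest.approx((0.9 - 1.5) / 1.5 * 100.0)

    def test_zero_extreme_period_skipped(self):
        periods = self._periods([0.0, 0.2])
        lo, hi = amplitude_range(0.98, periods, +1)
        assert lo == hi == pytest.approx(390.0, abs=1e-9)

    def test_requires_periods(self):
        with pytest.raises(ValueError):
            amplitude_range(1.0, [], +1)


class TestScreenPipeline:
    def test_constant_fixture_is_silent(self, flat_frame, schedules):
        report = screen(flat_frame, schedules["R1"], mode="experimental")
        assert report.failure_day is None
        assert all(r.abrupt_change_day is None for r in report.records)
        assert not any(r.risk_flag for r in report.records)

    def test_r1_gradual_fixture_warning_times(self, r1_gradual_frame, schedules):
        report = screen(r1_gradual_frame, schedules["R1"], mode="experimental")
        assert report.failure_day == 112
        gradual = {
            r.indicator: r for r in report.records if r.window == (101, 113)
        }
        assert gradual["ia_ba"].abrupt_change_day == 105
        assert gradual["ia_ba"].warning_time == 7
        assert gradual["vfa_total"].abrupt_change_day == 109
        assert gradual["vfa_total"].warning_time == 3

    def test_r1_sudden_fixture_warning_times(self, r1_sudden_frame, schedules):
        report = screen(r1_sudden_frame, schedules["R1"], mode="experimental")
        assert report.failure_day == 159
        sudden = {r.indicator: r for r in report.records if r.window == (121, 165)}
        assert sudden["vfa_total"].abrupt_change_day == 147
        assert sudden["vfa_total"].warning_time == 12
        assert sudden["ia_ba"].warning_time == 2

    def test_doubling_thresholds_cannot_add_flags(self, r1_gradual_frame, schedules):
        base = screen(r1_gradual_frame, schedules["R1"], mode="experimental")
        relaxed = screen(
            r1_gradual_frame,
            schedules["R1"],
            mode="experimental",
            thresholds=EXPERIMENTAL_THRESHOLDS.scaled(2.0),
        )
        n_base = sum(r.risk_flag for r in base.records)
        n_relaxed = sum(r.risk_flag for r in relaxed.records)
        assert n_relaxed <= n_base

    def test_screening_is_deterministic(self, r1_gradual_frame, schedules):
        a = screen(r1_gradual_frame, schedules["R1"]).to_frame()
        b = screen(r1_gradual_frame, schedules["R1"]).to_frame()
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_coupled_indicator_steadier_than_single(self, schedules):
        """IA/BA fluctuates less than IA through the full-load phase on all
        packaged fixtures, mirroring the observed stability of coupled
        alkalinity indicators."""
        for preset, sched in [
            (synthetic.preset_r1_gradual(), "R1"),
            (synthetic.preset_r1_sudden(), "R1"),
            (synthetic.preset_r2_gradual(), "R2"),
        ]:
            frame = synthetic.make_overload_fixture(preset)
            report = screen(frame, schedules[sched])
            recs = {r.indicator: r for r in report.records}
            assert recs["ia_ba"].fullload_rsd_mean < recs["IA"].fullload_rsd_mean

    def test_missing_ph_skips_failure_with_warning(self, flat_frame, schedules):
        report = screen(flat_frame.drop(columns=["ph"]), schedules["R1"])
        assert report.failure_day is None
        assert any("failure detection skipped" in w for w in report.warnings)
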