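"""Absorption curves: shapes, continuity, normalization, superposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucast.absorption import (
    FAST_EXPONENTIAL_SPEC,
    SLOW_EXPONENTIAL_SPEC,
    DoseEvent,
    MealEvent,
    MichaelisMentenParams,
    carb_curve,
    exponential_curve,
    haiya_dose_curve,
    haiya_rapid_curve,
    michaelis_menten,
    profile_curve,
    superpose_events,
)
from glucast.grid import GridSpec


class TestMichaelisMenten:
    @pytest.mark.parametrize(
        "vmax, km, s, expected",
        [(1.0, 1.0, 1.0, 0.5), (3.0, 2.0, 0.0, 0.0), (2.0, 0.5, 4.5, 1.8)],
    )
    def test_rate(self, vmax, km, s, expected):
        assert michaelis_menten(MichaelisMentenParams(vmax, km), s) == pytest.approx(expected)

    def test_bounded_by_vmax(self):
        p = MichaelisMentenParams(2.5, 0.1)
        assert michaelis_menten(p, 1e9) < p.vmax

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            MichaelisMentenParams(-1.0, 1.0)
        with pytest.raises(ValueError):
            michaelis_menten(MichaelisMentenParams(1.0, 1.0), -0.1)


class TestHaiyaCurves:
    @pytest.mark.parametrize(
        "curve_fn, t, expected",
        [
            (haiya_rapid_curve, 0.0, 0.25),
            (haiya_rapid_curve, 30.0, 1.25),
            (haiya_rapid_curve, 500.0, 0.0),
            (haiya_dose_curve, 10.0, 0.25),
            (haiya_dose_curve, 120.0, 1.25),
            (haiya_dose_curve, 240.0, 0.75),
        ],
    )
    def test_anchor_values(self, curve_fn, t, expected):
        assert curve_fn().value_at(t) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "curve_fn, breakpoints",
        [
            (haiya_rapid_curve, [5.0, 30.0, 120.0]),
            (haiya_dose_curve, [30.0, 120.0, 240.0]),
        ],
    )
    def test_continuity_at_breakpoints(self, curve_fn, breakpoints):
        """Adjacent branches agree to 1e-9 at every reconstructed breakpoint."""
        curve = curve_fn()
        eps = 1e-7
        for b in breakpoints:
            left = curve.value_at(b - eps)
            right = curve.value_at(b + eps)
            assert abs(left - right) < 1e-5  # linear branches: O(eps) slope gap
            assert abs(curve.value_at(b) - left) < 1e-5

    def test_incremental_strips_basal(self):
        curve = haiya_rapid_curve()
        assert curve.incremental_at(0.0) == pytest.approx(0.0)
        assert curve.incremental_at(30.0) == pytest.approx(1.0)
        assert curve.incremental_at(500.0) == 0.0


class TestExponentialCurve:
    def test_fast_peak_normalized(self):
        assert exponential_curve(FAST_EXPONENTIAL_SPEC).value_at(120.0) == pytest.approx(1.0)

    def test_slow_zero_before_onset(self):
        assert exponential_curve(SLOW_EXPONENTIAL_SPEC).value_at(30.0) == 0.0

    def test_monotone_rise(self):
        curve = exponential_curve(FAST_EXPONENTIAL_SPEC)
        t = np.linspace(15.0, 120.0, 200)
        v = curve.value_at(t)
        assert v[0] < v[-1]
        assert np.all(np.diff(v) > 0)

    def test_monotone_decay_and_near_zero_end(self):
        onset, peak, end = FAST_EXPONENTIAL_SPEC
        curve = exponential_curve(FAST_EXPONENTIAL_SPEC)
        t = np.linspace(peak, end, 200)
        v = curve.value_at(t)
        assert np.all(np.diff(v) < 0)
        assert v[-1] <= 0.01
        assert curve.value_at(end + 1.0) == 0.0

    def test_non_monotone_spec_rejected(self):
        with pytest.raises(ValueError):
            exponential_curve((120.0, 15.0, 300.0))


class TestProfileCurve:
    @pytest.mark.parametrize(
        "kind, lo_h, hi_h", [("rapid_lispro", 1.0, 2.0), ("nph", 6.0, 10.0)]
    )
    def test_argmax_in_published_peak_range(self, kind, lo_h, hi_h):
        curve = profile_curve(kind)
        t = np.linspace(0.0, curve.support_minutes, 2000)
        t_peak = t[np.argmax(curve.value_at(t))]
        assert lo_h * 60 <= t_peak <= hi_h * 60

    def test_zero_at_injection_and_beyond_duration(self):
        curve = profile_curve("nph")
        assert curve.value_at(0.0) == 0.0
        assert curve.value_at(curve.support_minutes + 1) == 0.0

    def test_peak_normalized_to_one(self):
        curve = profile_curve("rapid_lispro")
        t = np.linspace(0.0, curve.support_minutes, 5000)
        assert np.max(curve.value_at(t)) == pytest.approx(1.0, abs=1e-4)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown insulin kind"):
            profile_curve("ultralente")


class TestCarbCurve:
    @pytest.mark.parametrize(
        "calories, peak_min", [(450.0, 15.0), (500.0, 30.0), (700.0, 30.0), (900.0, 30.0), (1000.0, 60.0)]
    )
    def test_calorie_binned_peak_time(self, calories, peak_min):
        curve = carb_curve(calories)
        t = np.linspace(0.0, 240.0, 4801)
        assert t[np.argmax(curve.value_at(t))] == pytest.approx(peak_min, abs=0.1)

    def test_amplitude_is_calories_over_100(self):
        assert carb_curve(450.0).value_at(15.0) == pytest.approx(4.5)

    def test_support_is_four_hours(self):
        assert carb_curve(1000.0).value_at(300.0) == 0.0
        assert carb_curve(1000.0).support_minutes == 240.0

    def test_non_positive_calories_rejected(self):
        with pytest.raises(ValueError):
            carb_curve(0.0)


def _grid(length=60):
    return GridSpec(start=pd.Timestamp("2021-06-01 00:00"), length=length)


class TestSuperposition:
    def test_no_events_gives_zero_signal(self):
        sig = superpose_events([], lambda e: None, _grid(40))
        assert sig.values.shape == (40,)
        assert np.all(sig.values == 0.0)

    def test_bolus_peak_scaled_by_units(self):
        grid = _grid(80)
        curve = exponential_curve(FAST_EXPONENTIAL_SPEC)
        ev = DoseEvent(pd.Timestamp("2021-06-01 00:10"), "fast", 2.0)
        sig = superpose_events([ev], lambda e: curve, grid)
        k = np.argmax(sig.values)
        assert sig.values[k] == pytest.approx(2.0, abs=0.02)
        peak_time = grid.times[k]
        expected = ev.time + pd.Timedelta(minutes=120)
        assert abs(peak_time - expected) <= pd.Timedelta(minutes=5)

    def test_two_unit_boluses_equal_one_double_bolus(self):
        grid = _grid(80)
        curve = exponential_curve(FAST_EXPONENTIAL_SPEC)
        t = pd.Timestamp("2021-06-01 00:07")
        two = superpose_events(
            [DoseEvent(t, "fast", 1.0), DoseEvent(t, "fast", 1.0)], lambda e: curve, grid
        )
        one = superpose_events([DoseEvent(t, "fast", 2.0)], lambda e: curve, grid)
        np.testing.assert_allclose(two.values, one.values, atol=1e-12)

    def test_wrong_grid_step_rejected(self):
        bad = pd.Timedelta(minutes=10)
        with pytest.raises(ValueError):
            GridSpec(start=pd.Timestamp("2021-06-01"), length=5, step=bad)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 600, allow_nan=False),
                st.floats(0.5, 10, allow_nan=False),
                st.booleans(),
            ),
            min_size=0,
            max_size=6,
        )
    )
    def test_linearity_and_brute_force_oracle(self, raw_events):
        """Superposition = brute-force double loop, and is additive over event sets."""
        grid = _grid(100)
        start = pd.Timestamp("2021-06-01 00:00")
        fast = exponential_curve(FAST_EXPONENTIAL_SPEC)
        haiya = haiya_rapid_curve()
        events, curves = [], []
        for minutes, units, use_haiya in raw_events:
            events.append(DoseEvent(start + pd.Timedelta(minutes=minutes), "fast", units))
            curves.append(haiya if use_haiya else fast)
        curve_of = dict(zip((id(e) for e in events), curves))
        sig = superpose_events(events, lambda e: curve_of[id(e)], grid)

        # brute-force oracle: explicit loop over (grid point, event)
        expected = np.zeros(grid.length)
        for k, g in enumerate(grid.times):
            for ev, cv in zip(events, curves):
                dt = (g - ev.time) / pd.Timedelta(minutes=1)
                expected[k] += ev.units * cv.incremental_at(float(dt))
        np.testing.assert_allclose(sig.values, expected, atol=1e-9)

        # linearity: first half + second half == whole
        half = len(events) // 2
        a = superpose_events(events[:half], lambda e: curve_of[id(e)], grid)
        b = superpose_events(events[half:], lambda e: curve_of[id(e)], grid)
        np.testing.assert_allclose(a.values + b.values, sig.values, atol=1e-9)

    def test_meal_events_not_scaled_again(self):
        grid = _grid(60)
        ev = MealEvent(pd.Timestamp("2021-06-01 00:00"), 450.0)
        sig = superpose_events([ev], lambda e: carb_curve(e.calories), grid)
        assert np.nanmax(sig.values) == pytest.approx(4.5, abs=0.05)


class TestEventValidation:
    def test_negative_units_rejected(self):
        with pytest.raises(ValueError):
            DoseEvent(pd.Timestamp("2021-06-01"), "fast", -1.0)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            DoseEvent(pd.Timestamp("2021-06-01"), "medium", 2.0)

    def test_non_positive_calories_rejected(self):
        with pytest.raises(ValueError):
            MealEvent(pd.Timestamp("2021-06-01"), 0.0)


def test_curve_csv_export_round_trips(tmp_path):
    curve = carb_curve(700.0)
    path = tmp_path / "carb.csv"
    curve.to_csv(path, step_minutes=5.0)
    df = pd.read_csv(path)
    assert list(df.columns) == ["minutes_since_event", "activity"]
    np.testing.assert_allclose(df["activity"], curve.value_at(df["minutes_since_event"].to_numpy()))
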