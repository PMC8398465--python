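"""Signal conditioning: CGM joining, accelerometer feature, channel alignment."""

import numpy as np
import pandas as pd
import pytest

from glucast.grid import GRID_STEP, GridSignal, GridSpec
from glucast.signals import AccelStream, accel_std_feature, align_channels, join_cgm_days

START = pd.Timestamp("2021-06-01 08:00")


def _day_file(start, hours, missing=()):
    times = pd.date_range(start, periods=int(hours * 12) + 1, freq="5min")
    keep = [i for i in range(len(times)) if i not in missing]
    return pd.DataFrame(
        {"datetime": times[keep].astype(str), "glucose": 6.0 + 0.01 * np.arange(len(keep))}
    )


class TestJoinCgmDays:
    def test_two_contiguous_days_cover_48h_inclusive(self):
        f1 = _day_file(START, 24)[:-1]  # half-open day
        f2 = _day_file(START + pd.Timedelta(hours=24), 24)
        sig = join_cgm_days([f1, f2])
        assert sig.grid.length == 48 * 12 + 1  # 577
        assert sig.mask.all()

    def test_single_reading(self):
        sig = join_cgm_days([pd.DataFrame({"datetime": [str(START)], "glucose": [5.5]})])
        assert sig.grid.length == 1
        assert sig.mask.all()
        assert sig.values[0] == 5.5

    def test_one_missing_slot_masks_one_point(self):
        sig = join_cgm_days([_day_file(START, 1, missing={5})])
        assert sig.grid.length == 13
        assert (~sig.mask).sum() == 1
        assert not sig.mask[5]
        assert np.isnan(sig.values[5])

    def test_grid_times_exact_no_drift(self):
        sig = join_cgm_days([_day_file(START, 72)])
        deltas = np.diff(sig.grid.times.asi8)
        assert (deltas == GRID_STEP.value).all()

    def test_duplicate_reading_keeps_last(self):
        df = pd.DataFrame(
            {"datetime": [str(START), str(START)], "glucose": [5.0, 7.0]}
        )
        sig = join_cgm_days([df])
        assert sig.values[0] == 7.0

    def test_snap_tie_toward_later_grid_point(self):
        df = pd.DataFrame(
            {
                "datetime": [str(START), str(START + pd.Timedelta(minutes=2, seconds=30)),
                             str(START + pd.Timedelta(minutes=5))],
                "glucose": [5.0, 9.0, 6.0],
            }
        )
        sig = join_cgm_days([df])  # 2.5-min reading ties between points 0 and 1
        assert sig.values[1] == 6.0  # tie snapped later; last reading wins the collision
        assert sig.values[0] == 5.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            join_cgm_days([])

    def test_unsorted_rows_warn_and_sort(self):
        df = _day_file(START, 1).iloc[::-1]
        with pytest.warns(UserWarning, match="non-monotone"):
            sig = join_cgm_days([df])
        assert sig.mask.all()


def _stream(values_v, hz=100.0, start=START, l=None, s=None):
    n = len(values_v)
    ts = start + pd.to_timedelta(np.arange(n) / hz, unit="s")
    z = np.zeros(n)
    return AccelStream(pd.DatetimeIndex(ts), np.asarray(values_v, float),
                       z if l is None else l, z if s is None else s)


class TestAccelStdFeature:
    def test_constant_acceleration_gives_zero(self):
        stream = _stream(np.full(40_000, 981.0))
        grid = GridSpec(start=START + pd.Timedelta(minutes=5), length=1)
        sig = accel_std_feature(stream, grid)
        assert sig.mask[0]
        assert sig.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_alternating_unit_axis_gives_sigma_one(self):
        v = np.tile([1.0, -1.0], 20_000)
        stream = _stream(v)
        grid = GridSpec(start=START + pd.Timedelta(minutes=5), length=1)
        sig = accel_std_feature(stream, grid)
        assert sig.values[0] == pytest.approx(1.0)

    def test_window_consumes_exactly_30000_samples_at_100hz(self):
        # 30000 samples cover exactly 5 min; one fewer must mask the point
        grid = GridSpec(start=START + pd.Timedelta(minutes=5), length=1)
        full = _stream(np.random.default_rng(0).normal(size=30_001))
        assert accel_std_feature(full, grid).mask[0]
        short = AccelStream(full.timestamps[:-2], full.vertical[:-2],
                            full.lateral[:-2], full.sagittal[:-2])
        # dropping trailing samples leaves < 30000 in the window -> masked
        assert not accel_std_feature(short, grid).mask[0]

    def test_shift_invariance(self):
        rng = np.random.default_rng(42)
        v = rng.normal(size=35_000)
        grid = GridSpec(start=START + pd.Timedelta(minutes=5), length=1)
        a = accel_std_feature(_stream(v), grid).values[0]
        b = accel_std_feature(_stream(v + 981.0), grid).values[0]
        assert a == pytest.approx(b, rel=1e-9)

    def test_combines_axis_variances(self):
        rng = np.random.default_rng(7)
        n = 31_000
        v, l, s = rng.normal(size=(3, n))
        stream = _stream(v, l=l, s=s)
        grid = GridSpec(start=START + pd.Timedelta(minutes=5), length=1)
        got = accel_std_feature(stream, grid).values[0]
        ts = stream.timestamps
        sel = (ts > grid.start - pd.Timedelta(seconds=300)) & (ts <= grid.start)
        expected = np.sqrt(sum(x[np.asarray(sel)].std(ddof=0) ** 2 for x in (v, l, s)))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_stream_all_masked(self):
        stream = AccelStream(pd.DatetimeIndex([]), np.array([]), np.array([]), np.array([]))
        grid = GridSpec(start=START, length=10)
        sig = accel_std_feature(stream, grid)
        assert not sig.mask.any()
        assert np.isnan(sig.values).all()

    def test_per_axis_mode_returns_three_channels(self):
        stream = _stream(np.random.default_rng(1).normal(size=31_000))
        grid = GridSpec(start=START + pd.Timedelta(minutes=5), length=1)
        multi = accel_std_feature(stream, grid, per_axis=True)
        assert multi.channel_names == ["std_vertical", "std_lateral", "std_sagittal"]
        assert multi.values.shape == (1, 3)


def _sig(start, length, mask=None, fill=1.0):
    grid = GridSpec(start=start, length=length)
    m = np.ones(length, bool) if mask is None else np.asarray(mask, bool)
    return GridSignal(grid, np.full(length, fill), m)


class TestAlignChannels:
    def test_overlap_intersection(self):
        a = _sig(START, 101)  # indices 0..100
        b = _sig(START + 50 * GRID_STEP, 101)  # 50..150
        joint = align_channels({"glucose": a, "accel": b})
        assert joint.grid.start == START + 50 * GRID_STEP
        assert joint.grid.length == 51
        assert joint.mask.all()

    def test_all_valid_introduces_no_masking(self):
        a = _sig(START, 50)
        b = _sig(START, 50, fill=2.0)
        joint = align_channels({"a": a, "b": b})
        assert joint.mask.all()
        np.testing.assert_array_equal(joint.channel("b"), 2.0)

    def test_night_gaps_reproduced_exactly(self):
        mask = np.ones(100, bool)
        mask[30:55] = False  # night removal on the accel channel
        glucose = _sig(START, 100)
        accel = _sig(START, 100, mask=mask)
        joint = align_channels({"glucose": glucose, "activity": accel})
        np.testing.assert_array_equal(joint.mask, mask)

    def test_joint_mask_never_unmasks(self):
        rng = np.random.default_rng(3)
        m1, m2 = rng.uniform(size=(2, 80)) > 0.3
        joint = align_channels({"a": _sig(START, 80, m1), "b": _sig(START, 80, m2)})
        assert not (joint.mask & ~m1).any()
        assert not (joint.mask & ~m2).any()

    def test_offset_lattice_rejected(self):
        a = _sig(START, 20)
        b = _sig(START + pd.Timedelta(minutes=2), 20)
        with pytest.raises(ValueError, match="offset"):
            align_channels({"a": a, "b": b})

    def test_no_overlap_rejected(self):
        a = _sig(START, 10)
        b = _sig(START + pd.Timedelta(hours=10), 10)
        with pytest.raises(ValueError, match="overlap"):
            align_channels({"a": a, "b": b})
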