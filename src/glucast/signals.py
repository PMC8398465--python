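"""Conditioning of raw sensor streams onto the canonical 5-minute grid.

Three operations: joining per-day CGM files into one clock-synchronized
glucose channel, reducing the 100 Hz chest-accelerometer stream to a per-grid
activity-intensity feature (the standard deviation of the trailing five
minutes of acceleration — 30,000 samples at the nominal rate), and
intersecting channels onto a common grid so that the model only ever sees
fragments where every input signal is present (night-time accelerometer gaps
drop out here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GRID_STEP, GridSignal, GridSpec, MultiGridSignal

__all__ = ["AccelStream", "join_cgm_days", "accel_std_feature", "align_channels"]

#: Nominal accelerometer sampling interval (10 ms = 100 Hz).
ACCEL_NOMINAL_HZ = 100.0

#: Samples per 5-minute feature window at the nominal rate.
SAMPLES_PER_WINDOW_100HZ = 30_000


@dataclass
class AccelStream:
    """Raw 3-axis chest accelerometer samples (gal = cm/s²)."""

    timestamps: pd.DatetimeIndex
    vertical: np.ndarray
    lateral: np.ndarray
    sagittal: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        self.vertical = np.asarray(self.vertical, dtype=float)
        self.lateral = np.asarray(self.lateral, dtype=float)
        self.sagittal = np.asarray(self.sagittal, dtype=float)
        if not (len(self.vertical) == len(self.lateral) == len(self.sagittal) == n):
            raise ValueError("all three axes must have the same length as timestamps")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def nominal_rate_hz(self) -> float:
        """Sampling rate inferred from the median inter-sample gap."""
        if len(self) < 2:
            return ACCEL_NOMINAL_HZ
        gaps = np.diff(self.timestamps.asi8) / 1e9  # seconds
        med = float(np.median(gaps))
        return 1.0 / med if med > 0 else ACCEL_NOMINAL_HZ


def join_cgm_days(day_files: Sequence[pd.DataFrame]) -> GridSignal:
    """Join per-day CGM tables and clock-synchronize to the 5-minute grid.

    Each table needs ``datetime`` and ``glucose`` columns (mmol/L).  The output
    grid spans the earliest to the latest reading at 5-minute cadence; each
    reading is snapped to its nearest grid point (ties toward the later
    point), the last reading wins on collisions, and grid points with no
    reading are masked invalid.
    """
    if not day_files:
        raise ValueError("no CGM day files supplied")
    frames = []
    for df in day_files:
        if not {"datetime", "glucose"} <= set(df.columns):
            raise ValueError("CGM tables need 'datetime' and 'glucose' columns")
        df = df[["datetime", "glucose"]].copy()
        df["datetime"] = pd.to_datetime(df["datetime"])
        if not df["datetime"].is_monotonic_increasing:
            warnings.warn("non-monotone CGM timestamps within a day file; sorting", stacklevel=2)
            df = df.sort_values("datetime", kind="stable")
        frames.append(df)
    allrows = pd.concat(frames, ignore_index=True)
    if allrows.empty:
        raise ValueError("CGM day files contain no readings")
    start = allrows["datetime"].min()
    span = allrows["datetime"].max() - start
    length = int(np.floor(span / GRID_STEP + 0.5)) + 1
    grid = GridSpec(start=start, length=length)

    values = np.full(length, np.nan)
    mask = np.zeros(length, dtype=bool)
    for t, g in zip(allrows["datetime"], allrows["glucose"]):
        k = grid.index_of(t)
        if 0 <= k < length:
            values[k] = g  # last reading on a grid point wins
            mask[k] = True
    return GridSignal(grid, values, mask)


def accel_std_feature(
    stream: AccelStream, grid: GridSpec, per_axis: bool = False
) -> GridSignal | MultiGridSignal:
    """Physical-activity intensity: std of the trailing 5 minutes of acceleration.

    For each grid point the population standard deviation of the acceleration
    vector over the preceding five-minute window — 30,000 samples at the
    nominal 100 Hz rate — is computed as √(σ_v² + σ_l² + σ_s²), the total
    standard deviation of the 3-axis signal about its mean.  Being a spread
    measure it is invariant to constant offsets (gravity) on any axis.  Grid
    points whose trailing window is incomplete (night removal, stream edges)
    are masked invalid.

    With ``per_axis=True`` the three per-axis standard deviations are returned
    as a 3-channel signal instead of the combined scalar.
    """
    window = pd.Timedelta(seconds=300)
    n = len(stream)
    if n == 0:
        empty = np.full(grid.length, np.nan)
        nomask = np.zeros(grid.length, dtype=bool)
        if per_axis:
            vals = np.full((grid.length, 3), np.nan)
            return MultiGridSignal(grid, ["std_vertical", "std_lateral", "std_sagittal"], vals, nomask)
        return GridSignal(grid, empty, nomask)

    expected = int(round(300.0 * stream.nominal_rate_hz))
    ts = stream.timestamps.asi8
    axes = np.column_stack([stream.vertical, stream.lateral, stream.sagittal])

    values = np.full((grid.length, 3), np.nan)
    mask = np.zeros(grid.length, dtype=bool)
    for k, g in enumerate(grid.times):
        lo = np.searchsorted(ts, (g - window).value, side="right")
        hi = np.searchsorted(ts, g.value, side="right")
        if hi - lo < expected:
            continue  # incomplete trailing window
        seg = axes[lo:hi]
        values[k] = seg.std(axis=0, ddof=0)
        mask[k] = True

    if per_axis:
        return MultiGridSignal(
            grid, ["std_vertical", "std_lateral", "std_sagittal"], values, mask
        )
    combined = np.sqrt(np.nansum(values**2, axis=1))
    combined[~mask] = np.nan
    return GridSignal(grid, combined, mask)


def align_channels(signals: Mapping[str, GridSignal]) -> MultiGridSignal:
    """Intersect channels onto a common grid with a joint validity mask.

    All inputs must share the 5-minute step and lie on one common lattice
    (starts differing by a whole number of steps).  The output grid is the
    overlap of all input extents; a grid point is valid only where every
    channel is valid.  Absorption-derived channels are dense (valid
    everywhere on their grid) and therefore never introduce masking.
    """
    if not signals:
        raise ValueError("no channels to align")
    for name, sig in signals.items():
        if sig.grid.step != GRID_STEP:
            raise ValueError(f"channel {name!r} is not on a 5-minute grid")
    starts = {n: s.grid.start for n, s in signals.items()}
    base = min(starts.values())
    for name, st in starts.items():
        if (st - base) % GRID_STEP != pd.Timedelta(0):
            raise ValueError(f"channel {name!r} grid is offset from the common lattice")

    common_start = max(s.grid.start for s in signals.values())
    common_end = min(s.grid.end for s in signals.values())
    if common_end < common_start:
        raise ValueError("channel grids have no temporal overlap")
    length = int((common_end - common_start) / GRID_STEP) + 1
    grid = GridSpec(start=common_start, length=length)

    names = list(signals)
    values = np.empty((length, len(names)))
    mask = np.ones(length, dtype=bool)
    for j, name in enumerate(names):
        sig = signals[name]
        off = int((common_start - sig.grid.start) / GRID_STEP)
        values[:, j] = sig.values[off : off + length]
        mask &= sig.mask[off : off + length]
    return MultiGridSignal(grid, names, values, mask)
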