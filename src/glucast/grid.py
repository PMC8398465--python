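"""Canonical 5-minute time grid and gridded signals.

All conditioned channels in the pipeline live on a shared uniform grid with a
5-minute step, the native cadence of the CGM sensor.  A :class:`GridSignal`
carries a validity mask alongside its values: points with no sensor coverage
(CGM gaps, night-time accelerometer removal) are masked invalid and carry NaN,
never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The canonical grid step. Every channel is resampled to this cadence.
GRID_STEP = pd.Timedelta(minutes=5)

GRID_STEP_SECONDS = 300.0


@dataclass(frozen=True)
class GridSpec:
    """A uniform 5-minute time lattice.

    Parameters
    ----------
    start : pandas.Timestamp
        Time of the first grid point (timezone-naive local clock).
    length : int
        Number of grid points (>= 1).
    step : pandas.Timedelta
        Grid step; fixed at 5 minutes.
    """

    start: pd.Timestamp
    length: int
    step: pd.Timedelta = GRID_STEP

    def __post_init__(self) -> None:
        if self.step != GRID_STEP:
            raise ValueError(f"grid step must be exactly 5 minutes, got {self.step}")
        if self.length < 1:
            raise ValueError("grid length must be >= 1")

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.length, freq=self.step)

    @property
    def end(self) -> pd.Timestamp:
        return self.start + (self.length - 1) * self.step

    def index_of(self, t: pd.Timestamp) -> int:
        """Nearest grid index for a timestamp; ties snap toward the later point."""
        offset = (t - self.start) / self.step
        return int(np.floor(offset + 0.5))

    def minutes_since(self, t: pd.Timestamp) -> np.ndarray:
        """Minutes elapsed from ``t`` to each grid point (negative before ``t``)."""
        return ((self.times - t) / pd.Timedelta(minutes=1)).to_numpy(dtype=float)


@dataclass
class GridSignal:
    """One channel on the canonical grid, with a validity mask."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray  # True = valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.grid.length,) or self.mask.shape != (self.grid.length,):
            raise ValueError("values and mask must both have length grid.length")
        # invalid entries carry NaN, never a silent number
        self.values = np.where(self.mask, self.values, np.nan)

    @classmethod
    def dense(cls, grid: GridSpec, values: np.ndarray) -> "GridSignal":
        """An everywhere-valid signal (e.g. a superposed absorption channel)."""
        return cls(grid, values, np.ones(grid.length, dtype=bool))


@dataclass
class MultiGridSignal:
    """Several channels aligned on one grid with a joint validity mask."""

    grid: GridSpec
    channel_names: list[str]
    values: np.ndarray  # shape (length, n_channels)
    mask: np.ndarray  # shape (length,), True = valid on every masking channel
    channel_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.grid.length, len(self.channel_names)):
            raise ValueError("values must have shape (grid.length, n_channels)")
        if self.mask.shape != (self.grid.length,):
            raise ValueError("mask must have length grid.length")
        self.channel_index = {n: i for i, n in enumerate(self.channel_names)}

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_index[name]]

    def select(self, names: list[str]) -> "MultiGridSignal":
        """A view of a subset of channels sharing this grid and mask."""
        idx = [self.channel_index[n] for n in names]
        return MultiGridSignal(self.grid, list(names), self.values[:, idx], self.mask)
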