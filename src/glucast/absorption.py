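"""Physiological absorption curves and superposition of sparse events.

Insulin injections and meals are sparse, instantaneous log entries, yet their
physiological effect unfolds over hours.  This module turns each event into a
continuous absorption-activity curve — a piecewise-linear reconstruction of a
published delay-differential model for rapid insulin, manufacturer time-action
profiles, or a simple two-exponential rise/decay — and superposes dose-scaled
copies of the curves onto the canonical 5-minute grid.

All curves are non-negative with finite support.  The piecewise-linear rapid
insulin curves carry a 0.25 mU/L basal plateau; for superposition across
multiple boluses the *incremental* component (value minus basal inside the
support) is used so the basal level is not stacked once per injection, while
the raw curve remains available for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .grid import GridSignal, GridSpec

__all__ = [
    "AbsorptionCurve",
    "InsulinTypeSpec",
    "DoseEvent",
    "MealEvent",
    "MichaelisMentenParams",
    "INSULIN_PROFILES",
    "FAST_EXPONENTIAL_SPEC",
    "SLOW_EXPONENTIAL_SPEC",
    "michaelis_menten",
    "haiya_rapid_curve",
    "haiya_dose_curve",
    "exponential_curve",
    "profile_curve",
    "carb_curve",
    "superpose_events",
]


@dataclass(frozen=True)
class AbsorptionCurve:
    """A named scalar function of minutes-since-event with finite support.

    ``value_at`` is the raw curve (basal plateau included, if any);
    ``incremental_at`` subtracts the basal offset inside the support and is
    what :func:`superpose_events` accumulates.
    """

    name: str
    support_minutes: float
    _fn: Callable[[np.ndarray], np.ndarray]
    basal: float = 0.0

    def value_at(self, t):
        t = np.asarray(t, dtype=float)
        inside = (t >= 0) & (t <= self.support_minutes)
        out = np.where(inside, self._fn(np.clip(t, 0.0, self.support_minutes)), 0.0)
        return out if out.ndim else float(out)

    def incremental_at(self, t):
        t = np.asarray(t, dtype=float)
        inside = (t >= 0) & (t <= self.support_minutes)
        raw = np.where(inside, self._fn(np.clip(t, 0.0, self.support_minutes)), 0.0)
        out = np.where(inside, np.maximum(raw - self.basal, 0.0), 0.0)
        return out if out.ndim else float(out)

    def to_csv(self, path, step_minutes: float = 1.0) -> None:
        """Export (minutes_since_event, activity) for plotting/fixtures."""
        t = np.arange(0.0, self.support_minutes + step_minutes / 2, step_minutes)
        pd.DataFrame({"minutes_since_event": t, "activity": self.value_at(t)}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class InsulinTypeSpec:
    """Onset/peak/duration of an insulin preparation, in hours."""

    kind: str  # rapid_lispro | regular | nph
    onset_hours: float
    peak_hours: float
    duration_hours: float

    def __post_init__(self) -> None:
        if not (0 < self.onset_hours < self.peak_hours < self.duration_hours):
            raise ValueError(
                "insulin spec requires 0 < onset < peak < duration (hours), got "
                f"{self.onset_hours}/{self.peak_hours}/{self.duration_hours}"
            )


#: Midpoints of the published onset/peak/duration ranges per preparation.
INSULIN_PROFILES: dict[str, InsulinTypeSpec] = {
    "rapid_lispro": InsulinTypeSpec("rapid_lispro", 0.25, 1.5, 5.0),
    "regular": InsulinTypeSpec("regular", 0.75, 3.0, 7.0),
    "nph": InsulinTypeSpec("nph", 1.5, 8.0, 12.0),
}

#: Exponential rise/decay anchor times in minutes (onset, peak, end).
FAST_EXPONENTIAL_SPEC = (15.0, 120.0, 300.0)
SLOW_EXPONENTIAL_SPEC = (60.0, 360.0, 720.0)


@dataclass(frozen=True)
class DoseEvent:
    """An insulin injection: timestamp, class (fast/slow), units."""

    time: pd.Timestamp
    insulin_class: str  # "fast" | "slow"
    units: float

    def __post_init__(self) -> None:
        if self.insulin_class not in ("fast", "slow"):
            raise ValueError(f"insulin_class must be 'fast' or 'slow', got {self.insulin_class!r}")
        if not self.units > 0:
            raise ValueError("insulin units must be > 0")


@dataclass(frozen=True)
class MealEvent:
    """A meal: timestamp and estimated calories (kcal)."""

    time: pd.Timestamp
    calories: float

    def __post_init__(self) -> None:
        if not self.calories > 0:
            raise ValueError("meal calories must be > 0")


@dataclass(frozen=True)
class MichaelisMentenParams:
    vmax: float
    km: float

    def __post_init__(self) -> None:
        if not (self.vmax > 0 and self.km > 0):
            raise ValueError("Michaelis–Menten parameters must be positive")


def michaelis_menten(params: MichaelisMentenParams, substrate: float) -> float:
    """Saturating uptake rate v = Vmax·S / (Km + S); bounded above by Vmax."""
    if substrate < 0:
        raise ValueError("substrate concentration must be >= 0")
    return params.vmax * substrate / (params.km + substrate)


def _piecewise_linear(breaks: Sequence[float], values: Sequence[float]):
    b = np.asarray(breaks, dtype=float)
    v = np.asarray(values, dtype=float)

    def fn(t: np.ndarray) -> np.ndarray:
        return np.interp(t, b, v)

    return fn


def haiya_rapid_curve() -> AbsorptionCurve:
    """Piecewise-linear absorption of a rapid (Lispro) bolus, in mU/L.

    Basal 0.25 on [0, 5]; linear rise to the 1.25 peak at 30 min; linear fall
    back to 0.25 at 120 min; basal until 140 min; zero outside.
    """
    fn = _piecewise_linear([0, 5, 30, 120, 140], [0.25, 0.25, 1.25, 0.25, 0.25])
    return AbsorptionCurve("haiya_rapid", 140.0, fn, basal=0.25)


def haiya_dose_curve() -> AbsorptionCurve:
    """Dose-adapted variant of the rapid-insulin curve, support 480 min.

    Basal 0.25 on [0, 30]; rise to 1.25 at 120 min; fall to 0.75 at 240 min;
    slower fall back to 0.25 at 480 min; zero outside.
    """
    fn = _piecewise_linear([0, 30, 120, 240, 480], [0.25, 0.25, 1.25, 0.75, 0.25])
    return AbsorptionCurve("haiya_dose", 480.0, fn, basal=0.25)


def exponential_curve(
    spec: tuple[float, float, float], name: str = "exponential", amplitude: float = 1.0
) -> AbsorptionCurve:
    """Two-exponential absorption: saturating rise to the peak, decay to ~0.

    The rise is 1 − e^{−(t−onset)/τr} normalized to exactly ``amplitude`` at
    the peak, with τr = (peak − onset)/3; the decay is e^{−(t−peak)/τd} with
    τd chosen so the value at end-of-support is 1% of the peak.
    """
    onset, peak, end = (float(x) for x in spec)
    if not (0 <= onset < peak < end):
        raise ValueError(f"exponential spec must satisfy 0 <= onset < peak < end, got {spec}")
    tau_r = (peak - onset) / 3.0
    tau_d = (end - peak) / math.log(100.0)
    rise_norm = 1.0 - math.exp(-(peak - onset) / tau_r)

    def fn(t: np.ndarray) -> np.ndarray:
        rising = (1.0 - np.exp(-(t - onset) / tau_r)) / rise_norm
        falling = np.exp(-(t - peak) / tau_d)
        out = np.where(t < peak, np.where(t < onset, 0.0, rising), falling)
        return amplitude * out

    return AbsorptionCurve(name, end, fn)


def profile_curve(spec: Union[InsulinTypeSpec, str]) -> AbsorptionCurve:
    """Smooth time-action profile from onset/peak/duration range midpoints.

    Synthesized as a log-normal-shaped unimodal pulse with its mode at the
    peak midpoint and a 1%-of-peak tail at end of duration, peak normalized
    to 1, zero outside [0, duration].  Positively skewed, matching published
    insulin time-action profiles qualitatively.
    """
    if isinstance(spec, str):
        try:
            spec = INSULIN_PROFILES[spec]
        except KeyError:
            raise ValueError(
                f"unknown insulin kind {spec!r}; expected one of {sorted(INSULIN_PROFILES)}"
            ) from None
    peak_min = spec.peak_hours * 60.0
    dur_min = spec.duration_hours * 60.0

    def log_ratio(sigma: float) -> float:
        # log of f(duration)/f(peak) for a log-normal pdf with mode peak_min
        mu = math.log(peak_min) + sigma**2
        x = dur_min
        lf_x = -math.log(x) - (math.log(x) - mu) ** 2 / (2 * sigma**2)
        lf_m = -math.log(peak_min) - (math.log(peak_min) - mu) ** 2 / (2 * sigma**2)
        return lf_x - lf_m

    target = math.log(0.01)
    sigma = brentq(lambda s: log_ratio(s) - target, 1e-3, 5.0)
    mu = math.log(peak_min) + sigma**2

    def fn(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        tp = t[pos]
        log_pdf = -np.log(tp) - (np.log(tp) - mu) ** 2 / (2 * sigma**2)
        log_pdf_mode = -math.log(peak_min) - (math.log(peak_min) - mu) ** 2 / (2 * sigma**2)
        out[pos] = np.exp(log_pdf - log_pdf_mode)
        return out

    return AbsorptionCurve(f"profile_{spec.kind}", dur_min, fn)


def carb_curve(calories: float) -> AbsorptionCurve:
    """Carbohydrate digestion curve for a meal of the given calories.

    Exponential rise/decay over a 4-hour digestion window; the peak comes at
    15 min for light meals (< 500 kcal), 30 min for 500–900 kcal, and 60 min
    above 900 kcal; the peak amplitude is calories/100.
    """
    if not calories > 0:
        raise ValueError("calories must be > 0")
    if calories < 500:
        peak = 15.0
    elif calories <= 900:
        peak = 30.0
    else:
        peak = 60.0
    return exponential_curve((0.0, peak, 240.0), name="carb", amplitude=calories / 100.0)


Event = Union[DoseEvent, MealEvent]


def superpose_events(
    events: Iterable[Event],
    curve_for_event: Callable[[Event], AbsorptionCurve],
    grid: GridSpec,
) -> GridSignal:
    """Sum dose-scaled absorption curves from sparse events onto the grid.

    Each event contributes scale · incremental(curve, g − t_event) at every
    grid point g, where the scale is the injected units for insulin and 1 for
    meals (meal amplitude is already baked into the carb curve).  Events are
    not snapped: elapsed time is computed exactly, so a bolus between grid
    points keeps its true peak placement.  The result is an everywhere-valid
    channel that is zero wherever no event contributes.
    """
    if grid.step != pd.Timedelta(minutes=5):
        raise ValueError("superposition grid step must be exactly 5 minutes")
    total = np.zeros(grid.length, dtype=float)
    for ev in sorted(events, key=lambda e: e.time):
        curve = curve_for_event(ev)
        scale = ev.units if isinstance(ev, DoseEvent) else 1.0
        elapsed = grid.minutes_since(ev.time)
        total += scale * curve.incremental_at(elapsed)
    return GridSignal.dense(grid, total)
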