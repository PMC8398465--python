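"""Readers for the D1NAMO-style per-patient file layout.

One canonical CSV dialect is defined for the package (the same one the
synthetic cohort writes): per-day CGM files ``glucose/day_*.csv`` with
``datetime,glucose`` (ISO-8601 local time, mmol/L), an ``insulin.csv`` log
with ``datetime,type,units`` (type ∈ fast/slow), a ``food.csv`` log with
``datetime,calories`` and day-coverage accelerometer files ``accel/day_*.csv``
with ``datetime,vertical,lateral,sagittal`` in gal.  Exports of the real
dataset can be mapped onto this dialect with a column-rename adapter.

Timestamps are treated as a timezone-naive local clock throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .absorption import DoseEvent, MealEvent
from .grid import GridSignal
from .signals import AccelStream, join_cgm_days

__all__ = ["PatientRecord", "RunConfig", "load_patient"]

log = logging.getLogger("glucast")


@dataclass
class PatientRecord:
    """Everything loaded for one patient, plus a data-quality report."""

    patient_id: str
    cgm: GridSignal
    accel: AccelStream | None
    dose_events: list[DoseEvent]
    meal_events: list[MealEvent]
    quality: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for an experiment-grid run (YAML file or CLI flags)."""

    data: str
    out: str
    experiments: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    repeats: int = 10
    epochs: int = 150
    master_seed: int = 0
    use_activity: bool = True

    def __post_init__(self) -> None:
        bad = [e for e in self.experiments if e not in range(1, 8)]
        if bad:
            raise ValueError(f"unknown experiment ids {bad}; valid ids are 1-7")
        if self.repeats < 1 or self.epochs < 1:
            raise ValueError("repeats and epochs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path} must contain a mapping of settings")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}; valid: {sorted(known)}")
        if "experiments" in raw:
            raw["experiments"] = tuple(int(x) for x in raw["experiments"])
        return cls(**raw)


def _read_log(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        return pd.DataFrame(columns=required)
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path} is missing columns {sorted(missing)}")
    return df


def load_patient(root_dir: str | Path, patient_id: str) -> PatientRecord:
    """Load and validate one patient directory.

    Malformed rows are skipped with a logged warning; events outside the CGM
    time span are logged and dropped.  The quality report counts meals and
    doses, exact duplicate meal rows, and dropped rows — mirroring the
    incidence bookkeeping of the source cohort.
    """
    pdir = Path(root_dir) / patient_id
    day_files = sorted((pdir / "glucose").glob("day_*.csv"))
    if not day_files:
        raise FileNotFoundError(f"no CGM day files under {pdir / 'glucose'}")
    cgm = join_cgm_days([pd.read_csv(f) for f in day_files])
    span = (cgm.grid.start, cgm.grid.end)

    quality = {"n_cgm_days": len(day_files), "n_cgm_points": int(cgm.mask.sum())}

    ins = _read_log(pdir / "insulin.csv", ["datetime", "type", "units"])
    dose_events, skipped = [], 0
    for row in ins.itertuples(index=False):
        try:
            ev = DoseEvent(pd.Timestamp(row.datetime), str(row.type), float(row.units))
        except (ValueError, TypeError) as exc:
            log.warning("skipping malformed insulin row %r: %s", tuple(row), exc)
            skipped += 1
            continue
        if not span[0] <= ev.time <= span[1]:
            log.warning("dropping out-of-span insulin dose at %s", ev.time)
            skipped += 1
            continue
        dose_events.append(ev)

    food = _read_log(pdir / "food.csv", ["datetime", "calories"])
    n_duplicates = int(food.duplicated().sum())
    meal_events = []
    for row in food.itertuples(index=False):
        try:
            ev = MealEvent(pd.Timestamp(row.datetime), float(row.calories))
        except (ValueError, TypeError) as exc:
            log.warning("skipping malformed meal row %r: %s", tuple(row), exc)
            skipped += 1
            continue
        if not span[0] <= ev.time <= span[1]:
            log.warning("dropping out-of-span meal at %s", ev.time)
            skipped += 1
            continue
        meal_events.append(ev)

    accel_files = sorted((pdir / "accel").glob("day_*.csv"))
    accel: AccelStream | None = None
    if accel_files:
        frames = [pd.read_csv(f) for f in accel_files]
        acc = pd.concat(frames, ignore_index=True)
        acc["datetime"] = pd.to_datetime(acc["datetime"])
        acc = acc.sort_values("datetime", kind="stable")
        accel = AccelStream(
            pd.DatetimeIndex(acc["datetime"]),
            acc["vertical"].to_numpy(float),
            acc["lateral"].to_numpy(float),
            acc["sagittal"].to_numpy(float),
        )

    quality.update(
        {
            "n_doses": len(dose_events),
            "n_fast_doses": sum(e.insulin_class == "fast" for e in dose_events),
            "n_slow_doses": sum(e.insulin_class == "slow" for e in dose_events),
            "n_meals": len(meal_events),
            "n_duplicate_meal_rows": n_duplicates,
            "n_skipped_rows": skipped,
            "n_accel_samples": 0 if accel is None else len(accel),
        }
    )
    return PatientRecord(patient_id, cgm, accel, dose_events, meal_events, quality)
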