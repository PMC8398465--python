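"""Synthetic D1NAMO-layout cohort whose glucose is driven by meals and insulin.

Generates per-patient raw file sets in the exact dialects the signal readers
consume: per-day CGM CSVs (5-minute cadence, mmol/L), an insulin log (fast
boluses with meals, one daily slow dose), a meal log with realistic
corruption (occasional missing and duplicated records), and day-only 3-axis
accelerometer CSVs with night gaps.

The latent dynamics are a minimal two-state gluco-regulatory stand-in,
integrated by forward Euler at 1-minute resolution:

    dG/dt = −p1·(G − Gb) − SI·X·G + km·Ra(t) − ka·A(t)
    dX/dt =  p2·(D(t) − X)

where D(t) is the superposed two-exponential insulin absorption drive of the
logged boluses, Ra(t) the superposed carbohydrate digestion input of the
logged meals, and A(t) a daytime activity-bout process that the accelerometer
noise magnitude tracks.  Because the simulator's ground-truth kinetics reuse
the package's own exponential absorption curves, the piecewise-linear and
profile configurations act as model-mismatch probes downstream.

Everything is deterministic given (cohort seed, patient index): a fixed seed
reproduces byte-identical file sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .absorption import (
    FAST_EXPONENTIAL_SPEC,
    SLOW_EXPONENTIAL_SPEC,
    carb_curve,
    exponential_curve,
)

__all__ = ["SimParams", "CohortSpec", "simulate_patient", "simulate_cohort", "ground_truth_bundle"]


@dataclass(frozen=True)
class SimParams:
    """Dynamics parameters of the minimal gluco-regulatory model.

    Units: glucose mmol/L, time minutes.  Defaults give overnight basal
    equilibria near 4–6 mmol/L, postprandial excursions of 3–7 mmol/L and a
    modest activity-driven uptake, keeping simulated glucose inside the
    physiologic 2–25 mmol/L band.
    """

    basal_glucose: float = 6.5  # Gb, mmol/L
    glucose_decay: float = 0.02  # p1, 1/min, return-to-basal rate
    insulin_sensitivity: float = 0.0010  # SI, per activity-unit per min
    insulin_action_decay: float = 0.05  # p2, 1/min, absorption-to-action lag
    meal_gain: float = 0.030  # km, mmol/L per min per (kcal/100)
    activity_gain: float = 0.04  # ka, mmol/L per min at full activity intensity

    def __post_init__(self) -> None:
        if any(v <= 0 for v in asdict(self).values()):
            raise ValueError("all dynamics parameters must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs of the synthetic cohort."""

    n_patients: int = 6
    days_per_patient: int = 4
    meals_per_day: tuple[int, int] = (2, 5)  # inclusive bounds, drawn per day
    calorie_mean: float = 650.0
    calorie_sd: float = 250.0
    calorie_range: tuple[float, float] = (150.0, 1400.0)
    fast_units_per_100kcal: float = 1.0
    slow_units_range: tuple[int, int] = (10, 18)
    sensor_noise_sd: float = 0.3  # mmol/L
    night_start_hour: float = 23.0  # accelerometer off, no activity
    night_end_hour: float = 6.0
    missing_meal_prob: float = 0.10
    duplicate_meal_prob: float = 0.05
    activity_bouts_per_day: tuple[int, int] = (1, 3)
    accel_hz: float = 100.0
    accel_gravity_gal: float = 981.0
    params: SimParams = field(default_factory=SimParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.missing_meal_prob, self.duplicate_meal_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.days_per_patient < 1 or self.n_patients < 1:
            raise ValueError("need at least one patient and one day")


_START = pd.Timestamp("2021-06-01 00:00:00")


def _is_night(hour_of_day: np.ndarray, spec: CohortSpec) -> np.ndarray:
    return (hour_of_day >= spec.night_start_hour) | (hour_of_day < spec.night_end_hour)


def _draw_events(spec: CohortSpec, rng: np.random.Generator):
    """Meal and dose events (true physiological events, before log corruption)."""
    meal_slots = np.array([7.5, 12.5, 16.5, 20.0])  # typical hours
    meals, doses = [], []
    for day in range(spec.days_per_patient):
        day0 = _START + pd.Timedelta(days=day)
        n_meals = int(rng.integers(spec.meals_per_day[0], spec.meals_per_day[1] + 1))
        slots = rng.choice(len(meal_slots), size=min(n_meals, len(meal_slots)), replace=False)
        for s in sorted(slots):
            t = day0 + pd.Timedelta(hours=float(meal_slots[s] + rng.uniform(-0.75, 0.75)))
            cal = float(np.clip(rng.normal(spec.calorie_mean, spec.calorie_sd), *spec.calorie_range))
            meals.append({"datetime": t, "calories": round(cal)})
            units = float(np.clip(round(cal / 100.0 * spec.fast_units_per_100kcal), 1, 15))
            t_bolus = t + pd.Timedelta(minutes=float(rng.uniform(0, 10)))
            doses.append({"datetime": t_bolus, "type": "fast", "units": units})
        t_slow = day0 + pd.Timedelta(hours=22.0 + float(rng.uniform(-0.3, 0.3)))
        doses.append(
            {"datetime": t_slow, "type": "slow", "units": float(rng.integers(*spec.slow_units_range))}
        )
    meals.sort(key=lambda m: m["datetime"])
    doses.sort(key=lambda d: d["datetime"])
    return meals, doses


def _activity_profile(spec: CohortSpec, rng: np.random.Generator, minutes: np.ndarray) -> np.ndarray:
    """Activity intensity A(t) in [0, 1]: daytime ambient level plus bouts."""
    hours = (minutes / 60.0) % 24.0
    night = _is_night(hours, spec)
    A = np.where(night, 0.0, 0.05)
    for day in range(spec.days_per_patient):
        n_bouts = int(rng.integers(spec.activity_bouts_per_day[0], spec.activity_bouts_per_day[1] + 1))
        for _ in range(n_bouts):
            start = day * 1440 + rng.uniform(8.0, 20.0) * 60.0
            dur = rng.uniform(20.0, 60.0)
            intensity = rng.uniform(0.3, 1.0)
            in_bout = (minutes >= start) & (minutes < start + dur)
            A = np.where(in_bout, np.maximum(A, intensity), A)
    A[night] = 0.0
    return A


@dataclass
class _SimResult:
    spec: CohortSpec
    patient_index: int
    minutes: np.ndarray  # 1-min latent time axis (minutes from start)
    G: np.ndarray
    X: np.ndarray
    Ra: np.ndarray
    A: np.ndarray
    cgm_times: pd.DatetimeIndex
    cgm_values: np.ndarray  # latent + noise
    cgm_noise: np.ndarray
    meals: list[dict]  # true events
    doses: list[dict]
    meal_log: list[dict]  # corrupted log as written to disk
    corruption: dict


def _simulate(spec: CohortSpec, patient_index: int) -> _SimResult:
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(patient_index)]))
    n_min = spec.days_per_patient * 1440 + 1
    minutes = np.arange(n_min, dtype=float)

    meals, doses = _draw_events(spec, rng)
    A = _activity_profile(spec, rng, minutes)

    fast_curve = exponential_curve(FAST_EXPONENTIAL_SPEC)
    slow_curve = exponential_curve(SLOW_EXPONENTIAL_SPEC)
    D = np.zeros(n_min)
    for d in doses:
        elapsed = minutes - (d["datetime"] - _START) / pd.Timedelta(minutes=1)
        curve = fast_curve if d["type"] == "fast" else slow_curve
        D += d["units"] * curve.value_at(elapsed)
    Ra = np.zeros(n_min)
    for m in meals:
        elapsed = minutes - (m["datetime"] - _START) / pd.Timedelta(minutes=1)
        Ra += carb_curve(m["calories"]).value_at(elapsed)

    p = spec.params
    G = np.empty(n_min)
    X = np.empty(n_min)
    G[0] = p.basal_glucose
    X[0] = 0.0
    for k in range(n_min - 1):
        dG = (
            -p.glucose_decay * (G[k] - p.basal_glucose)
            - p.insulin_sensitivity * X[k] * G[k]
            + p.meal_gain * Ra[k]
            - p.activity_gain * A[k]
        )
        dX = p.insulin_action_decay * (D[k] - X[k])
        G[k + 1] = G[k] + dG
        X[k + 1] = X[k] + dX
    if G.min() < 1.0 or G.max() > 30.0:
        raise ValueError(
            "simulated glucose left the physiologic band "
            f"[{G.min():.2f}, {G.max():.2f}] mmol/L with parameters {p}"
        )

    cgm_idx = np.arange(0, n_min, 5)
    cgm_times = _START + pd.to_timedelta(minutes[cgm_idx], unit="m")
    cgm_noise = rng.normal(0.0, spec.sensor_noise_sd, size=len(cgm_idx))
    cgm_values = G[cgm_idx] + cgm_noise

    # corrupt the meal log (physiology already used the true meals)
    meal_log, n_missing, n_dup = [], 0, 0
    for m in meals:
        if rng.uniform() < spec.missing_meal_prob:
            n_missing += 1
            continue
        meal_log.append(dict(m))
        if rng.uniform() < spec.duplicate_meal_prob:
            meal_log.append(dict(m))
            n_dup += 1
    corruption = {"missing_meals": n_missing, "duplicated_meals": n_dup}

    return _SimResult(
        spec, patient_index, minutes, G, X, Ra, A,
        pd.DatetimeIndex(cgm_times), cgm_values, cgm_noise,
        meals, doses, meal_log, corruption,
    )


def _write_accel_day(path: Path, spec: CohortSpec, sim: _SimResult, day: int,
                     rng: np.random.Generator) -> int:
    """Day-coverage accelerometer CSV whose magnitude std tracks A(t)."""
    step_s = 1.0 / spec.accel_hz
    t0 = day * 1440.0
    sec = np.arange(t0 * 60.0, (t0 + 1440.0) * 60.0, step_s)
    hours = (sec / 3600.0) % 24.0
    keep = ~_is_night(hours, spec)
    sec = sec[keep]
    if sec.size == 0:
        return 0
    a_idx = np.minimum((sec / 60.0).astype(int), len(sim.A) - 1)
    sd = 0.05 + 4.0 * sim.A[a_idx]
    times = np.datetime64(_START.to_datetime64(), "us") + (sec * 1e6).astype("timedelta64[us]")
    df = pd.DataFrame(
        {
            "datetime": np.datetime_as_string(times, unit="ms"),
            "vertical": np.round(spec.accel_gravity_gal + rng.normal(0, 1, sec.size) * sd, 3),
            "lateral": np.round(rng.normal(0, 1, sec.size) * sd, 3),
            "sagittal": np.round(rng.normal(0, 1, sec.size) * sd, 3),
        }
    )
    df.to_csv(path, index=False)
    return len(df)


def simulate_patient(spec: CohortSpec, patient_index: int, root: str | Path) -> dict:
    """Write one patient's raw file set; returns the manifest entry.

    Layout under ``root/patient_NNN/``: ``glucose/day_DD.csv`` (datetime,
    glucose), ``insulin.csv`` (datetime, type, units), ``food.csv``
    (datetime, calories — the corrupted log), and ``accel/day_DD.csv``
    (datetime, vertical, lateral, sagittal at the configured rate, daytime
    only).
    """
    sim = _simulate(spec, patient_index)
    rng_accel = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(patient_index), 1])
    )
    pdir = Path(root) / f"patient_{patient_index:03d}"
    (pdir / "glucose").mkdir(parents=True, exist_ok=True)
    (pdir / "accel").mkdir(parents=True, exist_ok=True)

    files: list[str] = []
    day_labels = ((sim.cgm_times - _START).days).astype(int)
    for day in range(spec.days_per_patient):
        sel = day_labels == day
        df = pd.DataFrame(
            {
                "datetime": sim.cgm_times[sel].strftime("%Y-%m-%d %H:%M:%S"),
                "glucose": np.round(sim.cgm_values[sel], 3),
            }
        )
        f = pdir / "glucose" / f"day_{day + 1:02d}.csv"
        df.to_csv(f, index=False)
        files.append(str(f.relative_to(root)))

    ins = pd.DataFrame(
        {
            "datetime": [d["datetime"].strftime("%Y-%m-%d %H:%M:%S") for d in sim.doses],
            "type": [d["type"] for d in sim.doses],
            "units": [d["units"] for d in sim.doses],
        }
    )
    ins.to_csv(pdir / "insulin.csv", index=False)
    files.append(str((pdir / "insulin.csv").relative_to(root)))

    food = pd.DataFrame(
        {
            "datetime": [m["datetime"].strftime("%Y-%m-%d %H:%M:%S") for m in sim.meal_log],
            "calories": [m["calories"] for m in sim.meal_log],
        }
    )
    food.to_csv(pdir / "food.csv", index=False)
    files.append(str((pdir / "food.csv").relative_to(root)))

    for day in range(spec.days_per_patient):
        f = pdir / "accel" / f"day_{day + 1:02d}.csv"
        n = _write_accel_day(f, spec, sim, day, rng_accel)
        if n:
            files.append(str(f.relative_to(root)))
        else:
            f.unlink(missing_ok=True)

    return {
        "patient_id": f"patient_{patient_index:03d}",
        "patient_index": patient_index,
        "seed": int(spec.seed),
        "files": files,
        "n_meals_true": len(sim.meals),
        "n_meals_logged": len(sim.meal_log),
        "n_doses": len(sim.doses),
        "corruption": sim.corruption,
    }


def simulate_cohort(spec: CohortSpec, root: str | Path) -> dict:
    """Simulate every patient and write ``manifest.json`` at the cohort root."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    entries = [simulate_patient(spec, i, root) for i in range(spec.n_patients)]
    manifest = {
        "seed": int(spec.seed),
        "n_patients": spec.n_patients,
        "days_per_patient": spec.days_per_patient,
        "accel_hz": spec.accel_hz,
        "patients": entries,
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def ground_truth_bundle(spec: CohortSpec, patient_index: int) -> dict:
    """Noise-free latent trajectories for oracle tests.

    Returns the 1-minute latent time axis and the G, X, Ra, A trajectories,
    plus the CGM sample times, the injected sensor noise, and the true
    (uncorrupted) meal and dose event lists.
    """
    sim = _simulate(spec, patient_index)
    return {
        "minutes": sim.minutes,
        "G": sim.G,
        "X": sim.X,
        "Ra": sim.Ra,
        "A": sim.A,
        "cgm_times": sim.cgm_times,
        "cgm_values": sim.cgm_values,
        "cgm_noise": sim.cgm_noise,
        "meals": sim.meals,
        "doses": sim.doses,
        "meal_log": sim.meal_log,
    }
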