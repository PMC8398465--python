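"""The seven-configuration comparison harness.

Seven experiment configurations differ only in how the sparse insulin and
meal logs are pre-processed into continuous channels — raw event spikes,
two-exponential absorption curves, the piecewise-linear rapid-insulin model,
or manufacturer time-action profiles — while glucose and activity channels
are shared.  Every configuration is trained per patient, 10 repeats each,
reusing the same window split per (patient, repeat) so that scores are
comparable across configurations; aggregation follows the two-stage
reduce-over-repeats-then-over-patients scheme, and a one-way ANOVA over the
pooled per-experiment scores tests whether pre-processing matters at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .absorption import (
    FAST_EXPONENTIAL_SPEC,
    SLOW_EXPONENTIAL_SPEC,
    DoseEvent,
    MealEvent,
    carb_curve,
    exponential_curve,
    haiya_rapid_curve,
    profile_curve,
    superpose_events,
)
from .grid import GridSignal, GridSpec, MultiGridSignal
from .predictor import ModelSpec, build_model, train
from .windows import WindowSet, build_windows, split_windows

__all__ = [
    "ExperimentConfig",
    "EXPERIMENTS",
    "derive_channel_bank",
    "preprocess_record",
    "run_grid",
    "aggregate",
    "anova_across_experiments",
    "derived_seeds",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """One row of the configuration table.

    ``use_activity=False`` expresses the no-activity ablation of the base
    configuration (3 input channels) rather than a separate experiment id.
    """

    id: int
    fast_insulin_model: str  # raw | exponential | haiya | profile
    slow_insulin_model: str  # raw | exponential | profile
    food_model: str  # none | raw | exponential
    use_activity: bool = True

    def __post_init__(self) -> None:
        if self.fast_insulin_model not in ("raw", "exponential", "haiya", "profile"):
            raise ValueError(f"unknown fast insulin model {self.fast_insulin_model!r}")
        if self.slow_insulin_model not in ("raw", "exponential", "profile"):
            raise ValueError(f"unknown slow insulin model {self.slow_insulin_model!r}")
        if self.food_model not in ("none", "raw", "exponential"):
            raise ValueError(f"unknown food model {self.food_model!r}")

    @property
    def channel_names(self) -> list[str]:
        names = ["glucose"]
        if self.use_activity:
            names.append("activity")
        names.append(f"fast_{self.fast_insulin_model}")
        names.append(f"slow_{self.slow_insulin_model}")
        if self.food_model != "none":
            names.append(f"food_{self.food_model}")
        return names

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


#: The seven configurations compared in the study.
EXPERIMENTS: dict[int, ExperimentConfig] = {
    1: ExperimentConfig(1, "raw", "raw", "none"),
    2: ExperimentConfig(2, "exponential", "exponential", "none"),
    3: ExperimentConfig(3, "haiya", "exponential", "none"),
    4: ExperimentConfig(4, "exponential", "exponential", "raw"),
    5: ExperimentConfig(5, "exponential", "exponential", "exponential"),
    6: ExperimentConfig(6, "haiya", "exponential", "exponential"),
    7: ExperimentConfig(7, "profile", "profile", "exponential"),
}


def _raw_spikes(events, grid: GridSpec, value_of) -> GridSignal:
    """Raw event channel: the event's value at its nearest grid point."""
    values = np.zeros(grid.length)
    for ev in events:
        k = grid.index_of(ev.time)
        if 0 <= k < grid.length:
            values[k] += value_of(ev)
    return GridSignal.dense(grid, values)


def derive_channel_bank(
    glucose: GridSignal,
    activity: GridSignal,
    dose_events: Sequence[DoseEvent],
    meal_events: Sequence[MealEvent],
) -> MultiGridSignal:
    """Precompute every candidate channel on the glucose grid.

    Each configuration then selects a column subset, which guarantees that
    window admissibility (and hence the shared splits) is identical across
    configurations: absorption channels are dense and never mask, and the
    joint mask always includes the activity channel even for the no-activity
    ablation.
    """
    from .signals import align_channels

    joint2 = align_channels({"glucose": glucose, "activity": activity})
    grid = joint2.grid
    fast = [e for e in dose_events if e.insulin_class == "fast"]
    slow = [e for e in dose_events if e.insulin_class == "slow"]

    fast_exp = exponential_curve(FAST_EXPONENTIAL_SPEC, "fast_exponential")
    slow_exp = exponential_curve(SLOW_EXPONENTIAL_SPEC, "slow_exponential")
    haiya = haiya_rapid_curve()
    fast_prof = profile_curve("rapid_lispro")
    slow_prof = profile_curve("nph")

    channels: dict[str, np.ndarray] = {
        "glucose": joint2.channel("glucose"),
        "activity": joint2.channel("activity"),
        "fast_raw": _raw_spikes(fast, grid, lambda e: e.units).values,
        "fast_exponential": superpose_events(fast, lambda e: fast_exp, grid).values,
        "fast_haiya": superpose_events(fast, lambda e: haiya, grid).values,
        "fast_profile": superpose_events(fast, lambda e: fast_prof, grid).values,
        "slow_raw": _raw_spikes(slow, grid, lambda e: e.units).values,
        "slow_exponential": superpose_events(slow, lambda e: slow_exp, grid).values,
        "slow_profile": superpose_events(slow, lambda e: slow_prof, grid).values,
        "food_raw": _raw_spikes(meal_events, grid, lambda e: e.calories).values,
        "food_exponential": superpose_events(
            meal_events, lambda e: carb_curve(e.calories), grid
        ).values,
    }
    names = list(channels)
    values = np.column_stack([channels[n] for n in names])
    return MultiGridSignal(grid, names, values, joint2.mask)


def preprocess_record(record) -> MultiGridSignal:
    """Full conditioning of one loaded patient: raw streams → channel bank.

    Computes the activity feature on the glucose grid (an empty feature if
    the patient has no accelerometer data — every point then masks out) and
    derives all candidate insulin/food channels.
    """
    from .signals import AccelStream, accel_std_feature

    accel = record.accel
    if accel is None:
        accel = AccelStream(pd.DatetimeIndex([]), np.array([]), np.array([]), np.array([]))
    activity = accel_std_feature(accel, record.cgm.grid)
    return derive_channel_bank(record.cgm, activity, record.dose_events, record.meal_events)


def derived_seeds(master_seed: int, patient_index: int, repeat: int) -> tuple[int, int]:
    """(split_seed, train_seed) for one (patient, repeat) cell.

    Derived from the master seed with ``numpy.random.SeedSequence`` so the
    split — and therefore the test-set time instants — depends on the patient
    and the repeat but never on the experiment id.
    """
    ss = np.random.SeedSequence([int(master_seed), int(patient_index), int(repeat)])
    a, b = ss.generate_state(2)
    return int(a % 2**31), int(b % 2**31)


def run_grid(
    configs: Mapping[int, ExperimentConfig],
    patients: Mapping[str, MultiGridSignal],
    repeats: int = 10,
    master_seed: int = 0,
    trainer: Callable[[WindowSet, ExperimentConfig, int], float] | None = None,
    epochs: int = 150,
) -> pd.DataFrame:
    """Train every (experiment, patient, repeat) cell and collect test RMSEs.

    ``patients`` maps patient id to a precomputed channel bank
    (:func:`derive_channel_bank`).  Windows are enumerated once per patient;
    the split for a given (patient, repeat) is shared byte-for-byte across
    all configurations.  A custom ``trainer`` callable (windowset, config,
    seed) → rmse may replace the LSTM fit (e.g. for bookkeeping tests).
    Failed fits are recorded as NaN with the diagnostic message attached.
    """
    rows = []
    patient_ids = sorted(patients)
    window_cache = {
        pid: build_windows(patients[pid], glucose_channel="glucose")
        for pid in patient_ids
    }
    for p_idx, pid in enumerate(patient_ids):
        bank = patients[pid]
        examples = window_cache[pid]
        for repeat in range(repeats):
            split_seed, train_seed = derived_seeds(master_seed, p_idx, repeat)
            full_set = split_windows(examples, bank.channel_names, seed=split_seed)
            for exp_id, config in configs.items():
                ws = full_set.select_channels(config.channel_names)
                try:
                    if trainer is not None:
                        score = float(trainer(ws, config, train_seed))
                    else:
                        spec = ModelSpec(n_channels=config.n_channels, epochs=epochs)
                        model = build_model(spec, seed=train_seed)
                        score = train(model, ws, spec, seed=train_seed).test_rmse
                    diag = ""
                except (ValueError, FloatingPointError) as exc:
                    score, diag = np.nan, str(exc)
                rows.append(
                    {
                        "experiment_id": exp_id,
                        "patient_id": pid,
                        "repeat_index": repeat,
                        "rmse": score,
                        "diagnostic": diag,
                    }
                )
    table = pd.DataFrame(rows)
    expected = len(configs) * len(patient_ids) * repeats
    if len(table) != expected:
        raise RuntimeError(f"incomplete grid: {len(table)} rows, expected {expected}")
    return table


def _check_complete(table: pd.DataFrame) -> None:
    missing = table[table["rmse"].isna()]
    if not missing.empty:
        cells = [
            f"(exp {r.experiment_id}, patient {r.patient_id}, repeat {r.repeat_index})"
            for r in missing.itertuples()
        ]
        raise ValueError("score table has missing cells: " + ", ".join(cells))


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Two-stage summary per experiment.

    First reduce the repeats of each (experiment, patient) cell to its mean,
    min and max; then reduce over patients: mean of means, mean of minimums,
    minimum of minimums, mean of maximums, maximum of maximums.
    """
    _check_complete(table)
    per_patient = (
        table.groupby(["experiment_id", "patient_id"])["rmse"]
        .agg(["mean", "min", "max"])
        .reset_index()
    )
    out = (
        per_patient.groupby("experiment_id")
        .agg(
            mean_of_means=("mean", "mean"),
            mean_of_mins=("min", "mean"),
            min_of_mins=("min", "min"),
            mean_of_maxs=("max", "mean"),
            max_of_maxs=("max", "max"),
        )
        .reset_index()
    )
    return out


def anova_across_experiments(table: pd.DataFrame, alpha: float = 0.05) -> dict[str, float]:
    """One-way fixed-effects ANOVA over the pooled scores of each experiment.

    Each experiment's patients × repeats scores form one group (the patient
    factor is deliberately ignored, so with 7 groups of 60 the degrees of
    freedom are 6 and 413).  Returns F, p, the upper-α critical F and both
    degrees of freedom.
    """
    _check_complete(table)
    groups = [g["rmse"].to_numpy() for _, g in table.groupby("experiment_id")]
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 scores each")
    n_total = sum(len(g) for g in groups)
    df_between = k - 1
    df_within = n_total - k
    if all(np.ptp(g) == 0 for g in groups):
        grand = np.concatenate(groups)
        f_stat = 0.0 if np.ptp(grand) == 0 else float("inf")
        p_value = 1.0 if f_stat == 0.0 else 0.0
    else:
        f_stat, p_value = scipy.stats.f_oneway(*groups)
    return {
        "F": float(f_stat),
        "p": float(p_value),
        "F_critical": float(scipy.stats.f.ppf(1 - alpha, df_between, df_within)),
        "df_between": df_between,
        "df_within": df_within,
    }
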