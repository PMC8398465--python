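# glucast

Blood-glucose forecasting for type 1 diabetes with physiological
absorption-curve pre-processing and a small recurrent predictor.

People with type 1 diabetes log insulin injections and meals as instantaneous
events, but the body absorbs both over hours. A machine-learning model fed
the raw event spikes must learn those absorption kinetics from scratch;
`glucast` instead converts each event into a continuous absorption-activity
curve before training and measures how much the choice of curve is worth.
It is aimed at researchers working on CGM-based glucose prediction who want
a reproducible harness for comparing pre-processing strategies.

## What it does

- **Absorption models** — two-exponential rise/decay curves for fast
  (onset/peak/end 15/120/300 min) and slow (60/360/720 min) insulin,
  piecewise-linear rapid-insulin curves reconstructed from a published
  delay-differential approximation, time-action profiles synthesized from
  manufacturer onset/peak/duration ranges, and calorie-binned carbohydrate
  digestion curves (peak at 15/30/60 min depending on meal size, amplitude
  kcal/100). Sparse events are superposed linearly onto a 5-minute grid,
  scaled by injected units.
- **Signal conditioning** — CGM day files joined and clock-synchronized to
  the 5-minute grid; physical activity summarized as the standard deviation
  of the trailing 5 minutes (30,000 samples at 100 Hz) of 3-axis chest
  acceleration; channels intersected so the model only sees fragments where
  every signal is present (night-time accelerometer gaps drop out).
- **Forecasting** — sliding windows of 24 steps (2 h) predicting glucose
  60 min ahead (t+12), split 60/20/20 at random; a single-layer LSTM of 56
  memory units plus a 1-unit dense output (13664 + 57 weights at 4 input
  channels), implemented in numpy with full BPTT and Adam, trained with
  batch 16 for a fixed number of epochs on the RMSE objective, scores
  reported in mmol/L.
- **Experiment harness** — seven configurations differing only in the
  insulin/food pre-processing, run per patient with repeated random splits
  shared across configurations, aggregated two-stage (repeats, then
  patients) and compared with a one-way ANOVA.
- **Synthetic cohort** — a generator that emulates the target dataset's
  exact file layout (per-day CGM CSVs, insulin and meal logs with realistic
  missing/duplicated meal records, day-only 100 Hz accelerometer files)
  with glucose driven by a minimal two-state gluco-regulatory model, so the
  whole pipeline is exercisable without any data download.

## Worked example

Simulate a small synthetic cohort and compare the raw-input configuration
(1) against the fully pre-processed one (5, exponential insulin + food):

```sh
glucast simulate --patients 2 --days 4 --seed 7 --accel-hz 2 --out cohort/
glucast run-experiments --data cohort/ --experiments 1,5 \
    --repeats 2 --epochs 40 --seed 7 --out results/
```

which prints:

```
 experiment_id  mean_of_means  mean_of_mins  min_of_mins  mean_of_maxs  max_of_maxs
             1       1.132930      1.044630     1.025816      1.221229     1.409726
             5       0.875896      0.837901     0.799624      0.913892     0.950311
ANOVA: F=6.94 (critical 5.99 at df 1,6), p=0.0389
```

Reading this: each row aggregates test RMSE in mmol/L over 2 patients × 2
repeated splits. Feeding the model absorption curves instead of raw event
spikes lowers the mean RMSE from 1.13 to 0.88 mmol/L on this cohort, and
the one-way ANOVA over the pooled scores rejects equality of the two
configurations at α = 0.05 (F = 6.94 above the critical 5.99). Columns
follow the two-stage scheme: per-patient mean/min/max over repeats, then
mean (or extreme) across patients. `glucast report --scores
results/scores.csv --out report/` renders the table as markdown plus
per-experiment and per-patient box plots.

The library surface mirrors the pipeline: `glucast.absorption` (curves and
superposition), `glucast.signals` (grid conditioning), `glucast.windows`,
`glucast.predictor`, `glucast.experiments`, `glucast.synthetic_cohort`,
`glucast.io`. See `docs/methods.md` for the model, its assumptions, and
every numerical choice.

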