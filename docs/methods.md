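# Methods

## Problem

For a person with type 1 diabetes, the glucose level one hour ahead is
predictable in part from the last two hours of CGM readings, recent insulin
injections, recent meals, and physical activity. The obstacle for a small
recurrent model is representational: injections and meals appear in the logs
as isolated spikes, while their physiological effect is a smooth
several-hour process. `glucast` converts those sparse events into continuous
absorption-activity channels before training, and quantifies how much that
pre-processing is worth by comparing seven configurations that differ only
in the absorption model used.

## Absorption models

All curves map minutes-since-event to a non-negative, finite-support
activity and are superposed linearly across events, scaled by the injected
units (insulin) or with the calorie amplitude baked into the curve (meals).

- **Two-exponential curves.** Zero until onset, saturating rise
  `1 − e^(−(t−onset)/τ_r)` normalized to 1 at the peak, exponential decay
  after it. The anchor times are 15/120/300 min (onset/peak/end) for
  fast-acting insulin and 60/360/720 min for slow-acting. The time constants
  are not part of the anchor data; we set `τ_r = (peak − onset)/3` so the
  rise is visibly saturating, and `τ_d = (end − peak)/ln 100` so the value
  at end-of-support is exactly 1% of the peak, making the truncation to zero
  a true near-zero.
- **Piecewise-linear rapid-insulin curves.** Reconstructions of a published
  delay-differential approximation whose printed branch algebra is corrupted
  in the source; only the breakpoints and the 0.25 mU/L basal level are
  treated as ground truth, and continuity at every breakpoint is the
  reconstruction criterion. The rapid-bolus curve holds 0.25 on [0, 5] min,
  rises linearly to 1.25 at 30 min, falls back to 0.25 at 120 min and ends
  at 140 min; the dose-adapted variant peaks at 120 min and ends at 480 min.
  For superposition across multiple boluses the incremental component
  (value − 0.25 inside the support) is accumulated, so the basal plateau is
  not stacked once per injection; the raw curve is kept for plotting. Whether
  the original work superposed the basal per bolus or once globally is not
  recoverable; the incremental choice is the one that keeps superposition
  linear and signals decaying to zero.
- **Time-action profiles.** Built from the midpoints of published
  onset/peak/duration ranges (Lispro 0.25/1.5/5 h, Regular 0.75/3/7 h, NPH
  1.5/8/12 h) as a log-normal-shaped pulse with its mode at the peak
  midpoint and a 1%-of-peak tail at end of duration, peak normalized to 1.
  The log-normal shape gives the positive skew characteristic of measured
  insulin time-action profiles.
- **Carbohydrate digestion.** The two-exponential shape over a 4-hour
  support, peaking at 15 min below 500 kcal, 30 min for 500–900 kcal and
  60 min above 900 kcal, with peak amplitude calories/100.

Events are never snapped to the grid: each grid point evaluates the curve at
the exact elapsed time, so a bolus logged between grid points keeps its true
peak placement.

## Signal conditioning

Everything lives on a canonical 5-minute grid (the CGM cadence) with an
explicit validity mask; invalid points carry NaN, never a silent zero.

- CGM day files are concatenated and clock-synchronized: each reading snaps
  to its nearest grid point (ties toward the later point, last reading wins
  a collision); grid points with no reading are masked. Gaps are masked, not
  interpolated — downstream windowing only uses fragments where every input
  exists.
- The activity feature is the standard deviation of the trailing five
  minutes of 3-axis acceleration — 30,000 samples at the sensor's nominal
  100 Hz — computed as `√(σ_v² + σ_l² + σ_s²)`, the total standard deviation
  of the acceleration vector about its mean (population, ddof 0; with 3×10⁴
  samples the sample/population distinction is negligible). This single
  scalar is shift-invariant per axis (gravity drops out) and
  rotation-robust; a per-axis three-channel mode exists behind a switch.
  Points whose trailing window is incomplete — stream edges and the night
  hours when the chest belt is off — are masked.
- Channel alignment intersects extents and masks: a joint grid point is
  valid only where every masking channel is valid. Absorption channels are
  defined everywhere (zero without contributing events) and never mask.

## Windowing and splits

An example is the 24-step (2 h) block t−23…t of every channel with the
glucose at t+12 (60 min ahead) as target, sliding one step at a time. A
window is admitted only if all 24 input steps and the target step are valid;
the intermediate steps t+1…t+11 are not required. Examples are assigned to
train/validation/test at 60/20/20 uniformly at random (floor counts for
validation and test, remainder to train). The split is window-level random,
not chronological, matching the protocol being replicated; with overlapping
windows this induces optimistic absolute scores (train/test windows share
grid points), which is acceptable here because every configuration is
compared on identical splits — the comparison, not the absolute RMSE, is the
object of study.

Split seeds derive from `SeedSequence([master, patient_index, repeat])`, so
the test-set time instants for a given (patient, repeat) are identical
across all seven configurations, and the whole experiment grid is
reproducible from one master seed.

## Model and training

A single LSTM layer of 56 memory units over the 24×C input (C = 3, 4 or 5
channels; 3 covers the no-activity ablation) followed by a 1-unit dense
output. Parameter counts follow the standard gate formula `4·(u·(u+c)+u)`
for the recurrent layer (13664 at u=56, c=4) and `u+1` for the output (57).

The implementation is plain numpy: forward pass, full backpropagation
through time, and Adam (step 10⁻³, β 0.9/0.999, the conventional default
for this model class; the source protocol does not name its optimizer).
Initialization is Glorot-uniform input kernels, orthogonal recurrent
kernels, unit forget-gate bias. The objective is RMSE (gradient
`(ŷ−y)/(B·RMSE)` per batch); batch size 16, a fixed number of epochs
(default 150) with no early stopping, final-epoch weights retained and
validation loss recorded per epoch for monitoring only. Channels and target
are standardized by train-split mean/std and the scaling is inverted on
predictions, so reported RMSE is in raw mmol/L; a raw-unit mode exists
behind `ModelSpec(standardize=False)`. The backward pass is verified against
numerical differentiation in the test suite, and all randomness
(initialization, batch shuffling) flows from one integer seed, giving
bit-identical histories for identical seeds.

## Experiment harness

The seven configurations: (1) raw insulin spikes, no food; (2) exponential
fast+slow insulin; (3) piecewise-linear fast insulin, exponential slow; (4)
as 2 plus raw calorie spikes; (5) as 2 plus the carbohydrate curve; (6) as 3
plus the carbohydrate curve; (7) time-action profiles for both insulin types
plus the carbohydrate curve. All use glucose and the activity feature; the
no-activity ablation reuses configuration 1 with the activity channel
dropped.

Every candidate channel is precomputed once per patient into a channel bank;
a configuration selects a column subset. Since admissibility depends only on
the masking channels, the window set — and hence the shared split — is
byte-identical across configurations.

Aggregation is two-stage, per experiment: reduce each (experiment, patient)
cell's repeats to mean/min/max, then across patients take mean-of-means,
mean-of-mins, min-of-mins, mean-of-maxs and max-of-maxs. The ANOVA is
one-way fixed-effects over the pooled patients × repeats scores of each
experiment (7 groups of 60 in the full grid, df 6 and 413, critical F 2.12
at α = 0.05). Pooling ignores the repeated-measures structure (the same
patients appear in every group), so its p-value is anticonservative with
respect to the patient factor; it is implemented this way deliberately to
match the published degrees of freedom, and the caveat stands.

## Synthetic cohort

No public accession accompanies the protocol's cohort, so the package ships
a generator that emulates the layout exactly: per-day CGM CSVs, an insulin
log (fast boluses shortly after meals, one daily slow dose), a meal log, and
day-only accelerometer CSVs with night gaps. The meal log is corrupted the
way the real annotations are — each true meal is omitted with probability
0.10 and duplicated with probability 0.05 — while the physiology always sees
the true events.

Latent dynamics are a minimal two-state gluco-regulatory model (Euler,
1-minute steps):

    dG/dt = −p1·(G − Gb) − SI·X·G + km·Ra(t) − ka·A(t)
    dX/dt =  p2·(D(t) − X)

with D(t) the unit-scaled superposition of the package's own two-exponential
insulin curves, Ra(t) the superposed carbohydrate curves, and A(t) daytime
activity bouts (1–3 per day, 20–60 min, zero at night). Defaults: Gb = 6.5
mmol/L, p1 = 0.02 /min, SI = 0.001, p2 = 0.05 /min, km = 0.03, ka = 0.04;
sensor noise sd 0.3 mmol/L; 2–5 meals/day at jittered conventional meal
times, calories ~ N(650, 250²) clipped to [150, 1400] kcal. These keep
simulated glucose inside the physiologic 2–25 mmol/L band (the simulator
raises if the latent trajectory leaves [1, 30], naming the parameter set).

Because the simulator's insulin kinetics are the exponential curves, the
exponential configurations are well-specified for this cohort while the
piecewise-linear and profile configurations act as model-mismatch probes.
What passing tests show, therefore, is that the pipeline's ordering
mechanism works — a model given channels that track the latent insulin
action and meal appearance learns faster than one given spikes — not that
any particular RMSE value transfers to real patients. Real CGM noise is not
Gaussian, real meals are not logged at conventional times, and real
absorption varies between and within patients; none of that is emulated.

## Problem sizes

The default test and acceptance runs use a deliberately small instantiation
of the study design: cohorts of 2 patients × 4 days, one repeat per
configuration, 40 training epochs, and accelerometer files written at 2–5 Hz
(the feature definition is rate-aware: the 5-minute window is 30,000 samples
at the sensor's nominal 100 Hz, and the 100 Hz contract is tested on short
streams). The configuration-ordering property — exponential pre-processing
(config 5) beating raw inputs (config 1) on mean-of-means RMSE — is assessed
over 10 independently seeded cohort replicates and is expected in at least
7 of 10. The full 7 × 6 × 10 grid machinery (420 scores, 42 summaries) is
exercised with a stubbed trainer; running it with real training is a matter
of CLI flags and compute time.

## Known limitations

- The optimizer, input scaling and exponential time constants are package
  choices where the replicated protocol is silent; each is stated above.
- The window-level random split leaks overlapping windows across splits
  (inherited from the protocol; flagged, not fixed).
- The pooled one-way ANOVA ignores the patient factor (matching the
  published df); a mixed-effects treatment is out of scope.
- The numpy LSTM is single-threaded and eager; it is sized for this model
  class (tens of thousands of weights), not for larger architectures.
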