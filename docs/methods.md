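# Methods

## Problem setting

A continuous glucose monitor (CGM) worn by a hospitalized Type-2 diabetic
patient reports interstitial glucose in mg/dL every 5 minutes for several
days. The task is *personalized* short-horizon forecasting: using only one
patient's own recent readings, predict the glucose value 30 minutes ahead,
so that clinical staff can anticipate hypo- and hyperglycemia between ward
rounds. One model is trained per patient; no information crosses patients.

## Pipeline

1. **Cleaning** (`preprocessing.clean_trace`) — readings outside a validity
   range are removed and become missing grid slots. The default range is
   [40, 400] mg/dL (the full span seen in clinical summaries); the stricter
   [60, 400] device reporting range is selectable. Missing values are never
   imputed: imputation would fabricate inputs inside training windows.
2. **Regularization** (`preprocessing.regularize`) — timestamps are snapped
   to the nearest slot of the 5-minute grid; colliding observations keep
   the nearer-in-time one.
3. **Framing** (`framing.frame`) — each supervised sample pairs a
   `lookback = 7` window with the target `delay = 6` steps after the
   window's last element; windows slide with `step = 1`. A window or target
   touching a missing slot is skipped entirely, so for a gap-free trace of
   N points the sample count is exactly `N − lookback − delay + 1`.
4. **Chronological split** (`framing.chronological_split`) — the *raw
   series* is cut at the grid index nearest the train fraction (default
   0.7) and each segment is framed independently. No window or target
   crosses the cut; every training target precedes every test target, so
   test-period information cannot leak into training.
5. **Scaling** (`preprocessing.Scaler`) — per-patient z-score with the
   population (1/n) standard deviation, fitted only on the framed training
   inputs and targets; minmax and identity scaling are selectable. All
   reported metrics are computed after exact inversion, in mg/dL.
6. **Model** (`models`) — a sequence-processing block (simple RNN, GRU or
   LSTM; one or two layers; optionally bidirectional) followed by a dense
   hidden layer and a single linear regression unit. The baseline is one
   GRU layer with 32 units and *no* recurrent nonlinearity (the gates stay
   sigmoid), a 16-unit dense hidden layer, linear output.
7. **Evaluation** (`evaluation`) — RMSE (mg/dL), MAPE (%), and Clarke
   error-grid zones computed per patient; experiment tables report the
   unweighted cohort mean of per-patient metrics, with pair-pooled
   aggregation available for the Clarke grid.

## Recurrent networks

No deep-learning framework is part of this package's dependency set; the
recurrent layers, backpropagation through time, and the RMSprop and Adamax
optimizers are implemented in numpy (`cgmforecast.nn`) and verified against
numerical differentiation in the test suite. Conventions mirror the common
framework ones: GRU `h_t = z·h_{t−1} + (1−z)·h̃` with sigmoid update/reset
gates; LSTM with sigmoid input/forget/output gates and a forget-bias of 1;
the configurable activation ("linear" or "tanh") applies to the
candidate/cell path only. Weights use Glorot-uniform initialization under a
fixed seed; a bidirectional layer holds an independent time-reversed copy
and concatenates outputs, exactly doubling the recurrent parameter count.

## Training protocol

Mean-squared-error loss; mini-batches of 20 in chronological order
(shuffling re-draws the order each epoch from the run seed); 20 epochs;
RMSprop. The "improvement" experiment family varies these: batch 50,
shuffling, Adamax, 10 or 30 epochs.

The learning rate starts at 5e-3 and decays exponentially to 1/50th of the
initial value by the final epoch. The decay matters: glucose windows are
strongly autocorrelated, so the component of the regression map that acts
on *differences* of consecutive readings is ill-conditioned, and a
constant-rate RMSprop run settles into a bounce floor proportional to the
learning rate, stalling the baseline near the persistence forecaster. Large
early steps capture the gross input-output map; the decayed late steps
settle the slope-sensitive components. The schedule is configurable
(`TrainConfig.learning_rate`, `final_learning_rate`); setting the two equal
recovers a constant rate.

A NaN training loss aborts with a diagnostic pointing at input scaling and
the learning rate. Training is deterministic given
(ModelSpec, TrainConfig, SampleSet, seed) on a fixed platform.

## Baselines

The persistence forecaster — predict the window's last reading — is the
reference every learned model must beat. Over a 30-minute horizon on a
sinusoid of amplitude A and period P its RMSE has the closed form
`A·√2·|sin(π·30/P)|`, which the tests verify empirically. On low-noise
synthetic cohorts the trained GRU baseline's cohort-mean RMSE is required
(and tested) to be at or below the persistence mean.

## Synthetic cohort generator

The generator (`synthetic.simulate_trace`) emulates the statistical
structure of inpatient CGM traces; the scheduled reading at minute t is

    g(t) = basal + A·sin(2π(t_h − 10)/24)                 (circadian, peak ~16:00)
         + Σ_meals M·r̂(t − t_meal)                        (meal excursions)
         + AR(1) + white sensor noise,

clipped to the sensor range, after which dropout runs are deleted.
`r̂` is a double exponential `exp(−t/τ_decay) − exp(−t/τ_rise)` normalized
to unit peak (closed-form peak location), so a meal's magnitude parameter
is its peak height in mg/dL.

Per-patient defaults, drawn once per cohort (all configurable):

| parameter | default | rationale |
|---|---|---|
| basal level | N(170, 30) clipped to [100, 260] mg/dL | poorly controlled Type-2 inpatients; with meal uplift the pooled cohort mean lands near 193 mg/dL |
| circadian amplitude | U(8, 25) mg/dL | modest diurnal swing |
| meals | 3/day at 08:00, 12:00, 18:00 ± 30 min | hospital meal schedule |
| meal peak | U(50, 110) mg/dL, per-meal CV 0.2 | postprandial excursions |
| rise / decay τ | U(15, 30) / U(70, 120) min | fast rise, slow clearance |
| AR(1) | φ ~ U(0.85, 0.97), stationary SD U(8, 30) mg/dL | heterogeneous per-patient volatility (smooth vs spiky regimes) |
| sensor noise | U(2, 6) mg/dL | device measurement error |
| dropout | U(0.5, 2)/day runs, geometric mean length U(3, 8) steps | Bluetooth signal loss |
| sensor range | [40, 400] mg/dL | permissive default; [60, 400] selectable |
| wear time | U(2.6, 7.4) days | 3–7 day sensor sessions |

The AR(1) term is parameterized by its stationary standard deviation
(innovation SD = sd·√(1−φ²)), so turning the knob up provably increases
trace variance regardless of φ. Identical parameters (including the seed)
reproduce a trace bit-identically.

What the generator does *not* emulate: insulin dosing and its feedback on
glucose, physiological insulin–glucose dynamics (e.g. Bergman-type ODEs),
sensor drift and calibration steps, or meal-content variation beyond peak
height. Tests passing on synthetic cohorts therefore demonstrate that the
pipeline, training and evaluation machinery behave correctly and that the
models extract learnable temporal structure — not that any particular
clinical accuracy would be attained on real patients.

## Numerical and design choices

* Windows never span missing data (no interpolation); the framing count
  identity is exact and verified against brute-force enumeration.
* The chronological cut point is `round(fraction · span)` in grid indices;
  the boundary index belongs to the training segment.
* Clarke error grid: the standard programmatic rule chain with the 175/3
  mg/dL breakpoint, applied in fixed order A, E, C, D, else B; boundary
  ties resolve toward the earlier rule (a pair within 20% of reference is
  zone A even if it also sits on another zone's boundary). The rule chain
  is total: an exhaustive scan of integer pairs in {1..400}² is covered by
  the five zones.
* MAPE divides by the reference value; glucose is strictly positive so no
  epsilon guard is needed (non-positive references are rejected).
* Cohort summary tables report one row per patient (days to one decimal,
  max, min, mean over present readings) plus a Total row with summed days,
  global extrema and the pooled mean.
* Experiment cells derive their seeds from the experiment seed via
  `SeedSequence([seed, condition_index, patient_index])`, so any cell can
  be reproduced in isolation and a re-run from the stored config snapshot
  is bit-identical.
* Problem sizes: the shipped experiments use 20-patient cohorts with 2.6 to
  7.4 day traces and 32-unit recurrent layers — small enough that a full
  experiment family trains in minutes on one CPU while preserving the
  structure of the cohort analysis.

## Known limitations

* Hidden sizes, learning-rate schedule and epoch budget are package
  defaults chosen for desk-scale reproducibility, not tuned clinical
  settings; exact numeric agreement with any particular clinical cohort is
  not expected, since such data are not redistributable.
* Only classic Clarke error-grid analysis is implemented; the
  rate-of-change-aware continuous EGA variant is out of scope.
* Forecasts are single-scalar (one horizon per model); multi-step
  sequence-to-sequence prediction is out of scope.
* Meal and insulin event streams are not modeled as inputs; the forecaster
  sees glucose history only.
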