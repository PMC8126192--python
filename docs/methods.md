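# Methods

## Problem

People with type 1 diabetes repeatedly decide how much to eat or how much
insulin to bolus.  `bolusrec` inverts the usual glucose-forecasting problem:
given everything observed up to the present time `t` — CGM glucose at 5-minute
resolution, pump-recorded boluses and basal rates, self-reported meals — it
estimates the carbohydrate amount `C(t+10)` or the bolus dose `B(t+10)` that
would drive blood glucose to a user-chosen target `G(t+10+τ)` for a horizon
`τ ∈ {30, 35, …, 90}` minutes.  The 10-minute offset reflects the standard
advice to bolus 10 minutes before eating.

Four scenario datasets are built from the same streams: all carb events
(`carbs_pm_b`), carb events without an associated bolus (`carbs_m_b`, the
hypo-correction / snack population), all regular boluses (`bolus_pm_c`), and
boluses paired with a meal 10 minutes later (`bolus_p_c`, where the planned
carb amount is an extra input).  *Inertial* examples forbid any other
meal/bolus inside the prediction window `(t, t+10+τ]`; *unrestricted* examples
do not.

## Pre-processing

Smartphone meal timestamps are unreliable relative to pump bolus records, so
every bolus with a positive bolus-wizard carb entry claims the closest
unconsumed smartphone meal within ±60 min and re-times it to exactly
bolus+10 min, replacing its carb value with the bolus-wizard entry; if none is
found, a meal is created there.  Ties in time distance are broken by carb
closeness to the bolus-wizard amount, then by preferring the earlier meal;
boluses are processed chronologically and each smartphone meal can be claimed
once.  A meal already sitting at bolus+10 with the bolus-wizard carbs is left
alone, which makes the operation idempotent.  Boluses without carb input
(corrections) anchor nothing.

CGM gaps are filled by linear interpolation on the 5-minute grid, strictly
between the first and last measurement.  An example at `(t, τ)` is rejected
when the sample at `t` or at `t+10+τ` is interpolated, when more than 2
interpolated samples fall in `(t−60, t]`, or more than 12 in `(t−360, t]`
(both windows include `t`; the spec's "prior to t" is ambiguous and including
`t` only double-covers the present-time filter).

All channels are scaled to [0, 1] by per-channel min/max computed on the
training split only, without clipping, so out-of-range test values stay
informative.  The horizon feature is mapped linearly from [30, 90] min to
[0, 1]; the target glucose uses the glucose scaler, the ToD-average feature
the label scaler, and the planned-carbs feature the carbs scaler.

## Models

**Baselines.**  The global average predicts the subject's mean training label;
the time-of-day average keeps one mean per window — [12am,6am), [6am,10am),
[10am,2pm), [2pm,6pm), [6pm,12am) — and answers with the window overlapping
`t+10`, falling back to the global mean when a window has no training events.

**Two-LSTM chain.**  Encoder 1 (state size 32) is unrolled over the 72 steps
covering `(t−355, t]` with per-step inputs (glucose, carbs, bolus, basal).
Encoder 2's initial state (h and c) is a linear projection of encoder 1's
final hidden state; it is unrolled over the `(10+τ)/5` window steps with the
event channels only (carbs, bolus, basal — glucose is unobservable in the
future, and the channel is omitted rather than zero-filled).  The queried
event itself is masked out of the window channels (and for `bolus_p_c` the
paired meal is masked and carried only as the planned-carbs feature), so the
label never leaks into the inputs.  The concatenation
`[s1, s2, target BG, τ, ToD average (, planned carbs)]` feeds 2-3 ReLU layers
of width 64 with dropout after each hidden layer, then a linear output.  The
second encoder also runs for inertial examples (over all-zero channels): this
keeps one architecture and encodes τ through the unroll length.

**Residual stack.**  The chain is reused as a repeating block.  Block 1
receives the scaled glucose history; block b+1 receives block b's glucose
input minus block b's *backcast* (a 72-step reconstruction), while the
non-glucose channels and extra features pass to every block unchanged.  Each
block also emits a scalar *forecast*; the estimate is the sum of forecasts.
By default one joint linear layer of width 73 emits `[backcast, forecast]`
per block.  Up to 5 blocks are used, per-scenario defaults following the
tuned values (blocks 3-5, 2-5 hidden layers, dropout 0.2-0.5); the small-data
`carbs_m_b` scenario halves the recurrent and hidden widths (16/32).

**Loss.**  `MSE(estimate, label)` plus, for stacks, per-block supervision:
`(α/B)·Σ_b MSE(cumulative forecast through b, label)` and
`(β/B)·Σ_b MSE(backcast_b, glucose input of block b)` with `α = β = 1` by
default.  The exact form of the per-block terms is a design choice (the
cumulative-forecast target and the 1/B weights are ours) and is exposed as
configuration.  Blocks do not share weights by default; a `share_weights`
flag exists because a shared parameterization is markedly smaller and may
match some reported model sizes.

The models are implemented in NumPy on a small reverse-mode autodiff tape
(`bolusrec.autodiff`); the LSTM unroll is a single fused graph node with
hand-written backpropagation through time, which the gradient-correctness
test verifies against central differences at 1e-4 relative tolerance.

## Training protocol

Adam with a fixed learning rate of 0.001, mini-batch size 64 (batches are
horizon-homogeneous because the window length depends on τ), dropout, and
early stopping with a patience of 10 epochs on validation loss, restoring the
best-validation-epoch weights.  Each subject's record is split
chronologically: last 10 days test, preceding 10 days validation, remainder
training.  A generic model is pre-trained on the pooled training examples of
all subjects (each scaled with its own subject's scaler), then fine-tuned per
subject.  Runs repeat over 10 seeds; the *mean* score averages test RMSE/MAE
over seeds then subjects, the *best* score picks per subject the seed with
the lowest validation MAE — selection never sees test data.  Model
comparisons use a one-tailed Welch t-test (pooled-variance variant
available).

## Synthetic data generator

The real pump/CGM dataset this pipeline targets is under a data-use
agreement, so a simulator provides subjects with known ground truth.  It is a
*linear state-space* glucose model, not a physiological one: the deviation
from an equilibrium of 120 mg/dL decays by 5%/step (half-life ≈ 67 min, in
the range of published glucose-effectiveness estimates) and is driven by
per-step increments from triangular kernels — carbs peak at 45 min with
180 min support and potency 3.5 mg/dL per gram; insulin peaks at 75 min with
300 min support and potency equal to the subject's per-time-of-day insulin
sensitivity.  Kernel increments sum to 1, so with no reversion the
accumulated rise from a `c`-gram meal is exactly `c · k_c`.  Because the
model is linear in events, the exact dose/carbs needed to hit a target at
lag τ is one division by the unit response (kernel convolved with the decay):
this closed-form oracle round-trips through the forward simulation to
numerical precision and serves as the irreducible-error reference.

The generator reproduces the *logging pathology* the pre-processing exists
for: pump streams are ground-truth timed, a simulated bolus wizard doses
meals from per-ToD carb ratios/sensitivities (recommendation overridden with
probability 0.2 by a U(0.8, 1.2) factor, dual boluses with probability 0.05,
doses rounded to 0.1 u), while the smartphone meal log is jittered by
U(−30, +20) min, mis-estimated by a U(0.8, 1.2) factor (people misjudge
portions; this also gives the raw-vs-anchored ablation a realistic label-noise
component), and missing with probability 0.15.  Meals follow a
breakfast/lunch/dinner schedule with jitter, plus unbolused snacks, bedtime
snacks and a hypoglycemia-correction rule (BG < 70 → 16 g, no bolus), which
guarantees a usable no-bolus carb population.  CGM adds Gaussian noise
(sd 5 mg/dL) and day-level dropout gaps (probability 0.3, length 15-120 min).
Basal rates are piecewise-constant around 1 u/h but do not enter the glucose
dynamics (the equilibrium absorbs them); they exist so the basal input
channel is realistic and non-constant.

What a green test on this generator does *not* establish: fidelity to human
glucose physiology (no insulin-on-board accumulation, no meal-absorption
variability, no exercise or stress), or performance on the real DUA-protected
dataset.  It does establish that every pipeline stage is wired correctly and
that the models can learn an invertible event-to-glucose relationship better
than the time-of-day baseline.

## Numerical and design notes

- Events are binned to the 5-minute grid by nearest-point rounding, ties
  down; binning conserves carb/bolus/basal totals to 1e-9.
- The history window is 72 steps, `(t−355, t]`; "the previous 6 h up to and
  including now" is ambiguous between 72 and 73 and is fixed in config.
- The internal clock is integer minutes from record start; wall-clock
  time-of-day is carried separately for ToD features.
- Dual boluses stay in the input channels (they move glucose) but are never
  prediction labels.
- Early stopping treats ties as non-improvements; with a patience of 10 the
  run halts exactly 10 epochs after the last strict improvement.
- Identical score vectors in the model-comparison t-test give an undefined
  statistic; the comparison returns p = 0.5 (zero effect) in that case.
- Reduced-scale settings used by the test suite (3 subjects, 30 days, ~8-18
  epochs) exist purely to fit a CI budget; the protocol defaults are 10
  seeds, patience 10, max 500 epochs.

## Known limitations

- No insulin-on-board term in either the simulator or the simulated bolus
  wizard; correction advice on top of recent boluses is therefore more
  aggressive than a real pump's.
- The per-block auxiliary-loss form is one of several reasonable choices;
  alternatives (final-backcast-only, unweighted sums) are untested.
- Per-subject learning-rate/batch tuning is not re-searched; fixed defaults
  with config overrides stand in for it.
- A parameter-count helper reports exact trainable sizes; the default
  unshared 5-block stack is far larger than the smallest published
  recommendation models, and `share_weights` is provided for memory-bound
  deployments.
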