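# Methods

## Problem setting

Postprandial hyperglycemia — blood glucose at or above 140 mg/dL after a
meal — is an early marker of progression toward type 2 diabetes. For a
full-time working adult wearing a 15-minute CGM and a thigh-worn activity
sensor, and keeping lunch and work logs, the pipeline predicts three
outcomes of the lunch meal: the absolute 3-h area under the glucose curve
(AUC, mg/dL·h), the maximum postprandial glucose (MaxBGL, mg/dL) and the
binary hyperglycemia label. Every predictor input is computable from data
timestamped at or before lunch; the targets use only the postprandial
window. All clock windows (fasting 6–10 AM, overnight 12 AM–8 AM, the 3-h
postprandial window) are local-clock definitions, so timestamps are kept
timezone-naive throughout.

## CGM metrics

AUC and iAUC integrate the piecewise-linear interpolant of the trace.
Window endpoints that fall between samples are themselves interpolated, so
the trapezoid over the in-window knots equals the exact integral of the
interpolant; the test suite checks this against an independent
knot-refined dense-grid integration at 1e-9 relative tolerance. iAUC
splits segments at baseline crossings so the positive-part integral is
also exact. Choices worth noting:

- **Horizon** defaults to 3 h (the stated outcome definition); 2 h is a
  flag.
- **Baseline** for iAUC is glucose at meal time, linearly interpolated
  from the two bracketing samples; without a pre-meal bracketing sample
  iAUC is missing.
- **Gaps**: a contiguous CGM gap longer than 45 min inside a window marks
  the metric missing rather than silently integrating across it. This is
  a quality guard of this implementation; ingestion never interpolates.
- **Label**: hyperglycemia is operationalized as MaxBGL ≥ 140 mg/dL within
  the 3-h window (threshold inclusive). The alternative 2-h point-reading
  definition is obtainable via the horizon flag; the windowed-maximum
  reading is the default because it is the least surprising reading of a
  windowed outcome set.

## Feature engineering

The five feature sets share a 15-feature common block (fasting glucose =
window minimum 6–10 AM; overnight mean 12 AM–8 AM; lunch and work-start
clock times as fractional hours; work-from-home flag; BMI; day-of-week as
integer 0–6; and the nutrition-label facts). On top of it: six sensor
durations, one self-report score, four macronutrients, and the glycemic
load. The seven activPAL event classes map to three feature classes —
sedentary, seated transport and lying count as *sitting*, cycling counts
as *stepping* — a documented, configurable convention. Durations are kept
in seconds internally. Events straddling a window boundary contribute
only their in-window portion (verified against one-second brute-force
counting). Macronutrients are scaled by (1 − leftover fraction) before the
glycemic-load formula. The self-report score uses strictly previous days
of the same study phase, which makes each phase's first day undefined
under the `Self*`/`All` sets; such rows are dropped with a logged count.
The 12× standing weight in the score is implemented exactly as specified
for the source cohort's instrument.

## Synthetic cohort

The generator emulates the source study's shape: 10 adults (cohort BMI
32.8 ± 4.5), a Baseline phase followed by "stand more" and "move more"
intervention phases in per-participant random order, five (default)
workdays per phase with a delivered lunch, weekends generated but never
modeling rows. Its causal core is a meal-response model

G(t) = baseline + Σ_meals A · r((t − t_meal)/τ) + ε,  ε ~ N(0, noise_sd²),

with the gamma-shaped kernel r(u) = u·exp(1 − u) (r(0)=0, unit peak at
u=1), τ = 45 min, values clipped at a 40 mg/dL physiologic floor. The
lunch amplitude is

A = gl_effect·GL − stepping_effect·stepping_min + sitting_effect·sitting_h

clipped at zero, using the *consumed* glycemic load and the same
pre-lunch activity definitions the feature layer computes — so the
embedded signal is recoverable from the assembled features by
construction. Breakfast and dinner produce smaller background excursions
(amplitude gl_effect × a drawn background GL) so overnight and fasting
features vary realistically and a null-effect parameterization yields
perfectly flat traces.

Defaults: gl_effect 1.7 mg/dL per GL unit, stepping_effect 0.5 mg/dL per
minute, sitting_effect 1.2 mg/dL per hour, baseline 88 ± 7 mg/dL, sensor
noise 5 mg/dL. These magnitudes were chosen once to place hyperglycemia
prevalence near 40% of lunches (measured 41–46% across seeds), inside the
30–50% band in which class balancing is meaningfully exercised, with the
protective/risk directions (fiber and stepping lower, sitting and
glycemic load raise) that clinical literature reports. Self-reported work
percentages are the true sensor-derived percentages plus
truncated-Gaussian reporting error (sd 5 points), re-normalized in integer
tenths so the reported triple never exceeds 100.

What the generator does **not** emulate: insulin kinetics or any
physiological ODE, second-meal effects, circadian glucose drift, sleep
structure, sensor dropout and compression artifacts, or correlations
between diet quality and activity. Passing tests therefore demonstrate
pipeline correctness and signal recovery under rank-order-faithful
conditions, not clinical performance on real cohorts.

## Predictors and evaluation

Features are standardized with training-partition statistics only;
zero-variance columns are dropped with a record. The enumerated zoo is RF
with 10/50/100 trees, Ridge with α ∈ {1, 0.1, 0.01}, thirteen MLP layouts
(the largest: 160-80-40-40-40-40-20-10), and XGBoost at library defaults.
MLPs train with early stopping on a 10% validation split, at most 2000
iterations — a stability choice for ~10²-row data. An attention-tabular
("TabNet"-style) backbone is an optional plug-in family; the core package
raises a clear error if it is requested without an adapter.

NRMSE divides RMSE by the mean of the observed outcomes (range
normalization is behind a flag); tolerance fractions report the share of
test cases within 5/10/15/20% relative error. Classification is a
soft-voting ensemble (unweighted mean of RF, XGBoost and MLP class
probabilities; an exact tie resolves to the positive class) scored by
accuracy and macro precision/recall/F1.

Two transforms apply to training partitions only, and raise if handed
anything else: Gaussian jitter augmentation in scaled units (default
σ = 0.05, one jittered copy appended; "small" is otherwise unquantified,
and these values reproduce the augmentation-helps direction on synthetic
data) and a from-scratch ADASYN (k = 5 neighbors, z-scored metric,
minority spawn counts proportional to majority-neighbor fractions,
synthesis on segments between minority neighbors, parity within ±5%). No
ready-made ADASYN implementation is part of the supported dependency set,
so the neighborhood synthesis is implemented here directly and checked
geometrically in the tests. Split schemes (ratio with floor rounding,
balanced-test, 10-fold, leave-one-subject-out, leave-one-out) mark their
partitions; personalization moves exactly one positive and one negative
test row into training. Per-repetition seeds derive from the master seed
via `SeedSequence`. The default repetition count is 20 (the experiment
design it mirrors used 100); test-suite runs use 10–20 repetitions and the
10 × 6 × 3 cohort (150 complete rows) as their standard problem size.

## Language-model hybrids

Prompts consist of a fixed task description plus an `Input:` block
serializing the `All` feature row in fixed key order; only the block
varies between rows. Responses are cached by (provider, prompt-hash),
parsed for their first numeric token, retried twice, and a refusal marks
the provider failed for the run (refusing providers drop out of fusion).
The `Hybrid` variant appends one prediction column per available
provider, `Hybrid_v2` exactly the designated best provider's column (a
config key, not a constant), and `Max` additionally jitter-augments the
training partition. The offline provider is a deterministic mock whose
prediction is a linear function of glycemic load, stepping minutes and
fasting glucose plus prompt-keyed noise of configurable sd, letting tests
dial provider skill from oracle to useless; live HTTP adapters can be
registered but are deliberately untested here.

## Counterfactual explanations

Mutable features default to diet and activity, ranged to the observed
training min/max; BMI, day-of-week, fasting glucose, overnight mean,
work-from-home and the self-report score are immutable (history and
anthropometry cannot be retro-acted). The search draws a 5000-candidate
pool, each candidate perturbing 1–4 mutable features (geometric, mostly
1–2; 70% local Gaussian moves with sd = ¼ of the feature range, 30%
global redraws), keeps only class-flipping candidates, and greedily
selects k maximizing λ₂·(mean pairwise L1 diversity) − λ₁·(L1 proximity
to the query) in z-scored space, seeded throughout. λ₁ = 0.5, λ₂ = 1.0
and the budget are desk-scale choices. Distance metrics are L1 in
z-space, following the proximity convention of the diverse-counterfactual
literature this design follows; the "features changed" tolerance is 1e-6
in raw units. Because non-flipping candidates are discarded before a set
is returned, validity is 1.0 for every nonempty set; an infeasible query
returns an empty set with a diagnostic rather than fabricated rows.

Feature attribution is a permutation-sampling Shapley estimator with an
interventional value function against a drawn background sample. Each
sampled permutation telescopes, so per-row contributions sum exactly to
prediction minus background expectation for any permutation count; the
ranking averages mean |contribution| over independent seeded trials
(defaults: 5 trials, 25 background rows, 10 permutations). This estimator
was likewise written in-package because no tree-exact Shapley library is
part of the supported dependency set; for the small feature counts here
the sampling estimator's additivity is exact and its ranking stable.

## Known limitations

- Synthetic realism is rank-order only; absolute metric values on
  synthetic cohorts do not transfer to real data.
- The sampling Shapley estimator is O(rows × permutations × features ×
  background) model evaluations; for hundreds of features a tree-exact
  method would be preferable.
- The counterfactual search is gradient-free and in-range only; it will
  not extrapolate beyond observed feature ranges, by design.
- Ingestion assumes well-formed ISO-8601 electronic logs; transcription
  of handwritten records is out of scope.
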