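# glucolens

Postprandial glucose analytics for working adults wearing a continuous
glucose monitor (CGM) and a thigh-worn activity sensor. The package turns
four raw data streams — 15-minute CGM traces, activPAL-style activity
events, lunch food logs and self-reported work logs — into per-day feature
rows, predicts the 3-hour postprandial area under the glucose curve (AUC),
the maximum postprandial glucose (MaxBGL) and postprandial hyperglycemia,
and explains hyperglycemic predictions with diverse counterfactual
"treatment pathways".

It is aimed at researchers in metabolic health and digital phenotyping who
want a fully testable reference pipeline: because cohort data of this kind
are rarely shareable, the package ships a synthetic-cohort generator with
a known causal structure so every stage — ingestion, feature engineering,
prediction, explanation — can be validated end to end without any download.

## The quantities and models

For a lunch at time $t_0$ with glucose trace $G(t)$ (mg/dL):

- **AUC** $= \int_{t_0}^{t_0+3\mathrm{h}} G(t)\,dt$ (mg/dL·h, absolute,
  trapezoidal over the linear interpolant);
- **iAUC** $= \int_{t_0}^{t_0+3\mathrm{h}} \max(G(t)-G(t_0),0)\,dt$;
- **MaxBGL** $= \max_{[t_0,\,t_0+3\mathrm{h}]} G(t)$;
- **hyperglycemia** $= \mathbf{1}[\mathrm{MaxBGL} \ge 140\ \mathrm{mg/dL}]$.

Meals are summarized by their **glycemic load**,

$$\mathrm{GL} = 19.27 + 0.39\,\mathrm{netcarb} - 0.21\,\mathrm{fat}
- 0.01\,\mathrm{protein}^2 - 0.01\,\mathrm{fiber}^2$$

(grams, scaled by the fraction of the meal actually eaten). Behavioral
features are sitting/standing/stepping seconds from midnight to lunch and
from work start to lunch, plus a self-reported activity score
$\overline{\%\mathrm{walk}} + 12\,\overline{\%\mathrm{stand}}$ over prior
days of the same study phase. Five named feature sets (`Sensor+GL`,
`Sensor+Macro`, `Self+GL`, `Self+Macro`, `All`) combine these blocks.

Predictors are a fixed zoo — Random Forests (10/50/100 trees), Ridge
(α ∈ {1, 0.1, 0.01}), thirteen MLP layouts, XGBoost — evaluated by NRMSE
(RMSE / mean of observed) and error-tolerance fractions for regression,
and by a soft-voting RF+XGB+MLP ensemble with ADASYN training-set
balancing and Gaussian-jitter augmentation for classification. A
zero-shot language-model interface (with a deterministic mock provider
for offline work) supplies extra prediction columns for the hybrid
variants. Counterfactual explanations are generated by a seeded
random-restart search over actionable features only (diet and activity;
BMI, glucose history and the calendar are immutable) and scored by
validity, diversity, normalized distance and features changed, all in
standardized feature space.

## Worked example

```bash
glucolens simulate --out data --participants 10 --workdays-per-phase 6 --seed 1
glucolens features --dir data --out features.csv --set All
glucolens evaluate --features-csv features.csv --repetitions 20 --seed 0 --out report.csv
glucolens explain  --features-csv features.csv --query-id 3 -k 2 --seed 0 --out exp.json
```

`simulate` writes the four CSV sources (`cgm.csv`, `activpal_events.csv`,
`food_log.csv`, `work_log.csv`) plus `ground_truth.json` for 10
participants over three phases (180 lunches). `features` assembles 150
complete rows × 33 columns under the `All` set (each phase's first day
has no prior same-phase work log, so its self-report score is missing and
the row is dropped).

`evaluate` repeats the balanced-test design (10 real rows per class held
out; training set ADASYN-balanced) 20 times and prints the mean row:

```
repetition  seed  accuracy  precision  recall       f1
      mean     0    0.8275   0.848356  0.8275 0.824138
```

i.e. the soft-voting ensemble recovers the generator's embedded signal
with ~83% accuracy and macro-F1 0.82 on held-out real rows. A Random
Forest regressor on the same rows reaches AUC NRMSE 0.052 versus 0.087
for predicting the training mean, with 93% of test cases within 10%
relative error.

`explain` prints the quality metrics of the returned counterfactual set:

```
{"validity": 1.0, "diversity": 11.40, "normalized_distance": 6.63,
 "features_changed": 2.0}
```

Both returned alternatives flip the predicted class (validity 1.0), and on
average two features move. For this query — a day with zero stepping
before lunch — option 1 adds ~23 min of stepping; option 2 swaps standing
time for ~142 min of stepping. Directions match clinical understanding:
more stepping and fiber protect, more sitting and calories raise risk.

## Layout

- `src/glucolens/synthetic_cohort.py` — seeded cohort generator with known
  ground-truth effects
- `src/glucolens/log_ingest.py` — typed, validating CSV readers/writers
- `src/glucolens/glycemic_metrics.py` — AUC, iAUC, MaxBGL, labels
- `src/glucolens/behavior_features.py` — glycemic load, activity
  durations, the five feature sets
- `src/glucolens/predictors.py` — model zoo, metrics, ADASYN, augmentation,
  soft voting
- `src/glucolens/llm_hybrid.py` — prompt rendering, mock provider, hybrid
  fusion
- `src/glucolens/counterfactuals.py` — diverse counterfactual search,
  set metrics, Shapley-style feature ranking
- `src/glucolens/experiments.py` — split schemes, personalization,
  repetition harness
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
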