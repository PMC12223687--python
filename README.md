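# labscreen

Ranked prescreening of clinical-trial candidates from routine laboratory
time series.

## The problem

Recruiting participants for a trial — e.g. a bioequivalence study enrolling
patients whose blood work meets per-parameter eligibility ranges — starts
with *prescreening*: staff manually review candidate records to decide who is
worth inviting for a screening visit. When only a minority of the pool is
eligible, screening candidates in arbitrary order wastes most of that effort.

`labscreen` trains one probabilistic classifier per laboratory parameter
(hemoglobin, neutrophil %, platelets, bilirubin, AST, ALT, ALP, creatinine by
default) that predicts, from a patient's three most recent (value, date)
measurements, whether their *next* value will fall inside the eligibility
range. Candidates are then screened in order of descending predicted
probability, and the saving is quantified against random-order screening.

## Method

1. **Combination windows.** Hospital visits are aperiodic, so instead of
   fixed-stride windows, every chronologically ordered size-4 subset of a
   patient's series becomes a training instance: a series of *n* points
   yields C(*n*, 4) windows (10 points → 210). Each window carries 8 numbers
   — 4 (value, date) pairs; the first 3 pairs are features, the 4th is the
   target, and the label is whether the target *value* lies in the range.
   Values are min-max scaled on the training split; dates become
   |date − screening date| / *N* with *N* = 365.25 days.
2. **Rebalancing.** Window density mirrors visit frequency, not biology.
   Rows are projected onto the first principal component of the feature
   matrix, the score range is cut into 100 equal-width regions, at most
   1000 rows are kept per region (≤ 100,000 total), and the majority label
   is then downsampled to the minority count.
3. **Weighted ensemble.** Pluggable scikit-learn base learners (default:
   random forest, k-nearest-neighbours, logistic regression) are combined by
   greedy forward selection with replacement on a held-out selection set;
   weights are inclusion counts, so the ensemble's selection-set F1 never
   falls below the best single learner's.
4. **Screening economics.** For a pool of *N* candidates with *K* eligible,
   finding *M* eligible by random screening takes *M*(*N*+1)/(*K*+1) screens
   in expectation (negative hypergeometric). The package reports the ranked
   screens-to-target, a seeded Monte-Carlo random baseline with this closed
   form, and the workload reduction
   (random − ranked) / random.

All metrics (accuracy, sensitivity, specificity, precision, F1, rank-based
AUC with ties counted ½) are computed from first principles in
`labscreen.metrics`.

A seedable synthetic-cohort generator (`labscreen.synthetic`) produces
EMR-like extracts — aperiodic visits, per-parameter valid rates calibrated
anywhere in (0, 1) — so the whole pipeline is testable without patient data.

## Worked example

```python
from datetime import date
import labscreen as ls
from labscreen.preprocess import FEATURE_COLUMNS

cfg = ls.default_cohort_config(n_patients=300, seed=42, parameters=["hemoglobin"])
obs = ls.generate_cohort(cfg)
train = obs[obs["date"] <= date(2016, 12, 31)]
test = obs[obs["date"] > date(2016, 12, 31)]

spec = ls.NormalizationSpec.fit(train, screening_date=date(2018, 12, 31))
groups = ls.build_training_set(train, cfg.ranges, spec)
balanced = ls.PCRegionResampler(seed=42).resample(groups, FEATURE_COLUMNS)

model = ls.GreedyWeightedEnsembleClassifier(random_state=42)
model.fit(balanced[FEATURE_COLUMNS].to_numpy(), balanced["label"].to_numpy())

pool = ls.build_evaluation_set(test, cfg.ranges, spec, (date(2017, 1, 1), date(2018, 12, 31)))
probs = model.predict_proba(pool[FEATURE_COLUMNS].to_numpy())[:, 1]
rep = ls.compute_metrics(pool["label"].to_numpy(), probs)

pm = dict(zip(pool["patient_id"], probs))
vm = dict(zip(pool["patient_id"], pool["label"]))
out = ls.evaluate_screening(pm, vm, target_m=16, n_reps=2000, seed=42)
```

Output of the run above:

```
training groups: 56320 (valid fraction 0.232)
rebalanced: 25146 rows, labels {0: 12573, 1: 12573}
ensemble weights: {'random_forest': 0.444, 'knn': 0.333, 'logistic': 0.222}
application pool: 69 patients, 24 valid; AUC 0.940
target M=16: ranked screening needs 18 screens; random needs 45.0 ± 5.2 (closed form 44.8)
workload reduction: 60.0%
```

Reading: from a 300-patient synthetic cohort, 56,320 labeled windows were
augmented from the training years, rebalanced to 25,146 class-even rows, and
an ensemble (weights shown) was fitted. On the held-out period, 69 patients
had enough history to score; 24 were truly eligible at their final visit.
Ranking by predicted probability finds 16 eligible patients after 18 screens,
versus ~45 screens at random — a 60% workload reduction.

The same pipeline runs from the shell:

```bash
labscreen simulate --n-patients 300 --seed 42 --out cohort.csv
labscreen preprocess --in cohort.csv --screening-date 2018-12-31 --out prep/
labscreen train --in prep/ --out model.pkl --seed 42
labscreen run-all --out demo/ --n-patients 300 --seed 42   # end-to-end demo
```

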