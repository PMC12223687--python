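# Methods

This note documents the model, its assumptions, the defaults and the design
choices made where the problem left them open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting and labeling

The unit of data is a laboratory observation: (patient, parameter, value,
acquisition date). A value is *valid* (label 1) when it lies inside the
parameter's eligibility range, invalid (label 0) otherwise. Ranges are
closed intervals by default, because protocol tables print them as closed
("0–1.2 mg/dL"); open bounds are configurable per side. The shipped default
ranges cover the eight parameters of a typical bioequivalence screen. The
ALT default (40–41 U/L) reproduces its source verbatim but is almost
certainly a typographical error for 0–41 U/L; it is flagged in
`labscreen.ranges` and should be overridden in any real use.

A *patient* is a valid candidate only if every parameter model predicts
validity; `patient_level_validity` implements that conjunction, and treats a
missing parameter prediction as indeterminate rather than auto-valid — a
deliberate safety default, since silently passing unassessed patients would
inflate apparent eligibility.

## Combination windows

With aperiodic visits, consecutive-run windows of fixed length both waste
data and confound gap length with trend. Every chronologically ordered
size-k subset of a patient's series is therefore a window (k = 4 by
default), giving C(n, k) windows per n-point series. Windows are arbitrary
ordered subsets, not consecutive runs — the count 210 for a 10-point series
forces this reading (consecutive runs would give 7).

A window's 8 numbers are 4 (value, date) pairs. The first three pairs are
the features; the fourth is the target pair, and the training label is
whether the target *value* is in range. The phrase "last two values" in the
labeling description cannot apply literally to a (value, date) pair — a date
has no valid range — so the default labels on the 4th point's value only;
`strict_labels=True` additionally requires the 3rd value in range. The
default makes inference from three past points well-posed: at scoring time
the 4th (future) pair does not exist, so feature rows carry exactly the six
leading numbers and the screening date enters only through the date-offset
normalization.

Values are min-max scaled per parameter with extrema fitted on the
*training* split only; later values may map outside [0, 1] (clipping is
optional and off by default, preserving information about out-of-range
drift). Date offsets are |date − screening date| / N with N = 365.25 days,
i.e. offsets in years; N is configurable because nothing pins its value —
it only rescales one feature axis. The anchor is the screening date for both
training and inference, matching the normalization formula; anchoring on the
window's own last date is a config choice away (pass a different
`screening_date` when fitting the spec). Duplicate same-day observations
keep the last value of the day by default (configurable to the mean).

## Rebalancing

Window density mirrors visit frequency, so frequently observed patients
dominate the feature space. Correction proceeds in the narrative order:
coverage flattening first, then label equalization.

1. Rows are projected onto the first principal component of the 6-column
   feature matrix (sign fixed so the largest-|loading| coordinate is
   positive, for run-to-run determinism). The score range is split into R
   equal-width regions — equal width on the raw scores, the simplest reading
   — and at most s rows are drawn per region without replacement.
2. The majority label is downsampled uniformly to the minority count.

Defaults are R = 100 regions and s = 1000 per region. The stated source
parameters for this step are internally inconsistent (100 regions × 5000
per region = 500,000, yet a total of 100,000 is also stated); the defaults
here hit the stated *total* of 100,000, and both knobs are exposed so either
reading can be configured. Regions smaller than the quota contribute all
their rows; empty regions are logged, not errors.

## Classifier and ensembling

One binary classifier per parameter maps the six features to P(next value in
range). The base roster is deliberately small — a random forest (100 trees),
a standardized 25-NN, and a standardized logistic regression — because the
ensemble contract only needs diverse probabilistic learners; any
scikit-learn classifier with `predict_proba` can be slotted in.

Ensemble selection is Caruana-style forward stepwise with replacement: 20%
of the training rows are held out (label-stratified), each step adds the
learner that maximizes the selection metric (default F1 at threshold 0.5) of
the running probability average, and the best-scoring prefix defines the
weights as inclusion counts normalized to one. Because the first step picks
the best single learner and the best prefix is kept, the selection-set
metric never falls below the best base learner's. After weight selection the
base learners are refit on the full training set with weights frozen. The
evaluation threshold of 0.5 is an assumption — nothing specifies a tuned
threshold — and is configurable.

Metrics are computed in-house (`labscreen.metrics`): confusion counts at the
threshold (prediction 1 when p ≥ t), sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F1 as their harmonic mean, and AUC as the
Mann–Whitney concordance probability via average ranks (ties count ½),
which equals trapezoidal ROC integration. Degenerate denominators return
NaN with a warning rather than an arbitrary 0 or 1.

## Screening economics

Candidates are ranked by descending probability, ties broken by patient id
(determinism over unspecified behaviour). `screens_until` is the smallest
prefix containing M valid patients. The random baseline is the negative
hypergeometric draw count, reported three ways: seeded Monte-Carlo mean ± sd
over uniform permutations, the closed form M(N+1)/(K+1), and (implicitly) a
single permutation when `n_reps=1` — useful for parity with single-draw
reports, which can sit a full standard deviation from the expectation.
Workload reduction is (random − ranked)/random and may be negative when the
classifier misleads; it is reported, not clamped.

Pools are tagged by difficulty from their valid rate: case 1 below 50%,
case 2 from 50% to 60% inclusive (the band is read as closed at both ends),
case 3 above 60%. Probability histograms use 20 equal-width bins on [0, 1]
by default (the bin count is an artifact choice; the rightmost bin is
closed).

## Synthetic cohorts

The generator emulates the regime the pipeline assumes: hundreds to
thousands of patients, multi-year spans, aperiodic visits, eight parameters
with valid rates spanning roughly 0.30–0.88, heavy label imbalance. Per
patient, a visit count is drawn as `visits_min + Poisson(mean − min)` with
`visits_min = 4` (the windowing minimum), and inter-visit gaps in days are
gamma with mean 120 and sd 90 (dispersion 0 gives periodic visits; the only
stated fact about real schedules is that they are *not* periodic, so the gap
law is an artifact choice). Schedules that overrun the configured span fall
back to sorted distinct uniform days, which keeps dates in-span and
aperiodic.

Values follow `baseline + drift·years + noise` with patient-level
`baseline ~ N(μ, σ_b)` and i.i.d. `N(0, σ_n)` noise. Default drift is zero,
so the marginal is `N(μ, √(σ_b²+σ_n²))` and the baseline mean achieving a
target valid rate has a closed form, solved by bracketed root-finding
(`calibrate_baseline`; unattainable rates return the interval midpoint with
a flag). Nonzero drift shifts the marginal and the calibration becomes
approximate — documented, not hidden. Default spreads scale with range
width (σ_b = 0.25·width between patients, σ_n = 0.08·width within), making
recent values informative about the next one, which is the situation where
ranked prescreening can help. Default per-parameter target valid rates are
hemoglobin 0.30, neutrophils 0.77, platelets 0.83, bilirubin 0.88, AST 0.82,
ALT 0.87, creatinine 0.52 — spanning all three difficulty cases — and ALP
0.60, a mid-range choice where no application-pool rate was available.
Values are not clipped to physiologic bounds by default (clipping would
break the closed-form calibration); an optional clipping flag exists.

What the generator does *not* model: inter-parameter correlation, disease
progression, demographics, measurement-protocol changes over years. Passing
tests therefore show that the pipeline recovers structure *of this kind* —
patient-stable trajectories with additive noise — not that it performs at
any particular level on hospital EMR data.

## Problem sizes and numerical choices

The test suite and acceptance checks run end-to-end training at
250–400 patients with ~9 visits each and a single parameter per run — the
package's chosen scale for routine verification; the pipeline itself is
vectorized per (patient, parameter) series and handles cohorts orders of
magnitude larger. Determinism: every stochastic step (generator, split,
sampling, forest, baseline permutations) takes an explicit seed, and
rerunning a pipeline config reproduces the manifest byte-for-byte.
Tie-breaks are fixed (ranking by patient id, greedy selection by lowest
learner index, PC sign by largest loading). Known limitations: no
probability calibration, no joint multi-parameter model (one model per
parameter, patient-level validity by conjunction), no imputation of missing
labs, and no unit harmonization across laboratories.
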