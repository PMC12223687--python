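"""Shared test utilities: small cohort-to-screening runs used by several tests."""

from __future__ import annotations

from datetime import date

import numpy as np

from labscreen import (
    CohortConfig,
    EligibilityRange,
    GreedyWeightedEnsembleClassifier,
    NormalizationSpec,
    ParameterModel,
    PCRegionResampler,
    build_evaluation_set,
    build_training_set,
    compute_metrics,
    evaluate_screening,
    generate_cohort,
)
from labscreen.preprocess import FEATURE_COLUMNS

HGB_RANGE = EligibilityRange("hemoglobin", 13.0, 18.0, "g/dL")

TRAIN_CUTOFF = date(2016, 12, 31)
SCREENING_DATE = date(2018, 12, 31)
TEST_WINDOW = (date(2017, 1, 1), SCREENING_DATE)


def make_cohort_config(seed: int, informative: bool, n_patients: int = 250) -> CohortConfig:
    """One-parameter cohort; informative = patient-level spread dominates noise.

    The pure-noise variant sets the between-patient spread to zero, so a
    patient's history carries no information about the next value.
    """
    width = HGB_RANGE.high - HGB_RANGE.low
    if informative:
        model = ParameterModel(
            baseline_mean=None,
            baseline_sd=0.30 * width,
            noise_sd=0.05 * width,
            target_valid_rate=0.30,
        )
    else:
        model = ParameterModel(
            baseline_mean=None,
            baseline_sd=0.0,
            noise_sd=0.30 * width,
            target_valid_rate=0.30,
        )
    return CohortConfig(
        n_patients=n_patients,
        parameters={"hemoglobin": model},
        ranges={"hemoglobin": HGB_RANGE},
        visits_mean=9.0,
        gap_mean_days=60.0,
        gap_sd_days=45.0,
        seed=seed,
    )


def train_and_screen(seed: int, informative: bool = True, n_patients: int = 250):
    """Full single-parameter run: generate, window, rebalance, train, screen.

    Returns ``(metrics_report, screening_outcome, model)`` where metrics are
    computed on the held-out application-test pool (features from the 3 points
    preceding each patient's most recent post-cutoff observation, truth from
    that final observation).
    """
    cfg = make_cohort_config(seed, informative, n_patients)
    obs = generate_cohort(cfg)
    train_obs = obs[obs["date"] <= TRAIN_CUTOFF]
    test_obs = obs[obs["date"] > TRAIN_CUTOFF]

    spec = NormalizationSpec.fit(train_obs, screening_date=SCREENING_DATE)
    groups = build_training_set(train_obs, cfg.ranges, spec)
    balanced = PCRegionResampler(seed=seed).resample(groups, FEATURE_COLUMNS)

    model = GreedyWeightedEnsembleClassifier(random_state=seed)
    model.fit(balanced[FEATURE_COLUMNS].to_numpy(), balanced["label"].to_numpy())

    pool = build_evaluation_set(test_obs, cfg.ranges, spec, TEST_WINDOW)
    probs = model.predict_proba(pool[FEATURE_COLUMNS].to_numpy())[:, 1]
    labels = pool["label"].to_numpy(dtype=int)
    report = compute_metrics(labels, probs)

    prob_map = dict(zip(pool["patient_id"], probs))
    valid_map = dict(zip(pool["patient_id"], labels))
    target_m = max(1, int(0.7 * labels.sum()))
    outcome = evaluate_screening(prob_map, valid_map, target_m, n_reps=400, seed=seed)
    return report, outcome, model


def brute_force_auc(labels, scores) -> float:
    """Pairwise concordance AUC oracle: ties count 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
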