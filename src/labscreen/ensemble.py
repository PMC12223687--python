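"""Per-parameter validity classifiers and greedy weighted ensembling.

One binary classifier is trained per laboratory parameter: given the three
most recent normalized (value, date-offset) pairs, predict the probability
that the patient's next value falls inside the eligibility range. Base
learners are pluggable scikit-learn probabilistic classifiers; on top of
them, ensemble selection (forward stepwise with replacement on a held-out
selection set, weights = inclusion counts) picks a convex combination of
their probability outputs that maximizes a validation metric (default F1).
By construction the first step picks the best single learner and the best
prefix is kept, so the selection-set metric never falls below the best base
learner's.

A patient is a valid trial candidate only if *all* parameter models predict
validity; :func:`patient_level_validity` applies that conjunction.
"""

from __future__ import annotations

import pickle
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .metrics import compute_metrics

__all__ = [
    "default_learners",
    "fit_learner",
    "greedy_weighted_ensemble",
    "GreedyWeightedEnsembleClassifier",
    "predict_validity",
    "patient_level_validity",
    "save_model_bundle",
    "load_model_bundle",
]


def default_learners(random_state: int | None = None) -> list[tuple[str, BaseEstimator]]:
    """The shipped base-learner roster: tree ensemble, nearest-neighbor, logistic.

    Any list of (name, probabilistic classifier) pairs with unique names can
    replace it.
    """
    return [
        ("random_forest", RandomForestClassifier(n_estimators=100, random_state=random_state)),
        (
            "knn",
            Pipeline(
                [("scale", StandardScaler()), ("knn", KNeighborsClassifier(n_neighbors=25))]
            ),
        ),
        (
            "logistic",
            Pipeline(
                [("scale", StandardScaler()), ("logit", LogisticRegression(max_iter=1000))]
            ),
        ),
    ]


def fit_learner(estimator: BaseEstimator, X, y) -> BaseEstimator:
    """Fit a clone of a probabilistic classifier on binary-labeled features."""
    X, y = check_X_y(X, y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = clone(estimator)
    model.fit(X, y)
    if not hasattr(model, "predict_proba"):
        raise TypeError("base learners must expose predict_proba")
    return model


def _score(metric: str, labels: np.ndarray, probs: np.ndarray, threshold: float) -> float:
    rep = compute_metrics(labels, probs, threshold=threshold)
    try:
        return float(getattr(rep, metric))
    except AttributeError:
        raise ValueError(f"unknown selection metric {metric!r}") from None


def greedy_weighted_ensemble(
    base_probs,
    labels,
    metric: str = "f1",
    n_iterations: int = 25,
    threshold: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Forward stepwise ensemble selection with replacement.

    ``base_probs`` is (n_learners, n_samples): each row a learner's predicted
    probability of the positive class on the selection set. At each step the
    learner whose inclusion maximizes the metric of the running probability
    average is added (a learner may be added repeatedly); the best-scoring
    prefix wins and weights are its inclusion counts normalized to 1.

    Returns ``(weights, selection_score)``.
    """
    P = np.asarray(base_probs, dtype=float)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("base_probs must be (n_learners, n_samples) with >= 1 learner")
    y = np.asarray(labels, dtype=int)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    n_learners = P.shape[0]

    chosen: list[int] = []
    running = np.zeros(P.shape[1])
    step_scores: list[float] = []
    for _ in range(n_iterations):
        cand_scores = [
            _score(metric, y, (running + P[j]) / (len(chosen) + 1), threshold)
            for j in range(n_learners)
        ]
        j_best = int(np.nanargmax(cand_scores))
        chosen.append(j_best)
        running = running + P[j_best]
        step_scores.append(cand_scores[j_best])

    best_len = int(np.argmax(step_scores)) + 1  # earliest maximum
    counts = np.bincount(chosen[:best_len], minlength=n_learners)
    weights = counts / best_len
    return weights, float(step_scores[best_len - 1])


class GreedyWeightedEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Weighted ensemble of probabilistic classifiers, scikit-learn style.

    Parameters
    ----------
    learners : list of (name, estimator) or None
        Base roster; ``None`` uses :func:`default_learners`.
    metric : str
        Selection metric maximized on the held-out selection set
        ("f1", "auc" or "accuracy").
    n_iterations : int
        Steps of forward selection with replacement.
    validation_fraction : float
        Fraction of the training data held out (label-stratified) for
        ensemble selection.
    threshold : float
        Probability cutoff for ``predict`` and thresholded metrics.
    random_state : int or None
        Seeds the split and any stochastic base learners.

    Attributes
    ----------
    learners_ : list of (name, fitted estimator)
        Base learners refit on the full training data.
    weights_ : ndarray
        Nonnegative convex weights over the roster (sum to 1).
    selection_score_ : float
        Metric of the winning ensemble on the selection set; never below the
        best entry of ``learner_selection_scores_``.
    learner_selection_scores_ : dict
        Each base learner's own selection-set metric.
    classes_ : ndarray
        The two class labels, sorted.
    """

    def __init__(
        self,
        learners: Sequence[tuple[str, BaseEstimator]] | None = None,
        metric: str = "f1",
        n_iterations: int = 25,
        validation_fraction: float = 0.2,
        threshold: float = 0.5,
        random_state: int | None = None,
    ) -> None:
        self.learners = learners
        self.metric = metric
        self.n_iterations = n_iterations
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.random_state = random_state

    def _roster(self) -> list[tuple[str, BaseEstimator]]:
        roster = (
            list(self.learners) if self.learners is not None else default_learners(self.random_state)
        )
        if not roster:
            raise ValueError("learner roster must not be empty")
        names = [n for n, _ in roster]
        if len(set(names)) != len(names):
            raise ValueError("learner names must be unique within an ensemble")
        return roster

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary labels required")
        roster = self._roster()

        X_tr, X_sel, y_tr, y_sel = train_test_split(
            X,
            y,
            test_size=self.validation_fraction,
            stratify=y,
            random_state=self.random_state,
        )
        fitted = [(name, fit_learner(est, X_tr, y_tr)) for name, est in roster]
        pos = 1  # index of classes_[1] in predict_proba columns
        sel_probs = np.stack([m.predict_proba(X_sel)[:, pos] for _, m in fitted])
        y_sel_bin = (y_sel == self.classes_[1]).astype(int)
        self.learner_selection_scores_ = {
            name: _score(self.metric, y_sel_bin, sel_probs[i], self.threshold)
            for i, (name, _) in enumerate(fitted)
        }
        weights, score = greedy_weighted_ensemble(
            sel_probs,
            y_sel_bin,
            metric=self.metric,
            n_iterations=self.n_iterations,
            threshold=self.threshold,
        )
        self.weights_ = weights
        self.selection_score_ = score
        # refit the base learners on all training data with frozen weights
        self.learners_ = [(name, fit_learner(est, X, y)) for name, est in roster]
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "learners_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; the ensemble was fitted with "
                f"{self.n_features_in_}"
            )
        p1 = np.zeros(X.shape[0])
        for w, (_, model) in zip(self.weights_, self.learners_):
            if w > 0:
                p1 += w * model.predict_proba(X)[:, 1]
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        p1 = self.predict_proba(X)[:, 1]
        return self.classes_[(p1 >= self.threshold).astype(int)]


def predict_validity(model: GreedyWeightedEnsembleClassifier, X) -> np.ndarray:
    """Probability that each feature row's next value will be in range."""
    return model.predict_proba(X)[:, 1]


def patient_level_validity(
    predictions: Mapping[str, int],
    required_parameters: Sequence[str] | None = None,
) -> int | None:
    """Conjunction of per-parameter validity predictions for one patient.

    Returns 1 only if every prediction is 1, and 0 as soon as any prediction
    is 0. If ``required_parameters`` lists parameters with no prediction (or
    a prediction is None), the patient is indeterminate (``None``) rather
    than auto-valid — unless an explicit 0 already settles the answer.
    """
    if not predictions:
        raise ValueError("at least one parameter prediction is required")
    values = dict(predictions)
    if any(v == 0 for v in values.values() if v is not None):
        return 0
    missing = any(v is None for v in values.values())
    if required_parameters is not None:
        missing = missing or any(p not in values for p in required_parameters)
    return None if missing else 1


def save_model_bundle(path, models: Mapping[str, GreedyWeightedEnsembleClassifier], spec=None) -> None:
    """Persist fitted per-parameter ensembles (and the normalization spec)."""
    with open(path, "wb") as fh:
        pickle.dump({"format": "labscreen-bundle-1", "models": dict(models), "spec": spec}, fh)


def load_model_bundle(path) -> dict:
    with open(path, "rb") as fh:
        bundle = pickle.load(fh)
    if bundle.get("format") != "labscreen-bundle-1":
        raise ValueError("not a labscreen model bundle")
    return bundle
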