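"""Binary-classification metrics computed from first principles.

The pipeline reports accuracy, sensitivity (recall of the valid class),
specificity, precision, F1 and AUC for every parameter model. Confusion
counts are taken at a probability threshold (default 0.5, prediction = 1 when
p >= threshold). AUC is the Mann–Whitney concordance probability — the chance
that a random valid case scores above a random invalid one, ties counted 1/2
— computed from average ranks, which equals trapezoidal integration of the
ROC curve.

Degenerate denominators (no positives, no negatives, no predicted positives)
yield NaN for the affected metric with a warning, except F1 which is 0 when
there are positives or predicted positives but no true positives.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricsReport", "compute_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return asdict(self)


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(labels, probs, threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics and rank-based AUC for binary labels."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and probs must be 1-D and aligned")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary 0/1")
    if not np.all((p >= 0) & (p <= 1)):
        raise ValueError("probabilities must lie in [0, 1]")

    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))

    n_pos, n_neg = tp + fn, tn + fp
    accuracy = (tp + tn) / len(y) if len(y) else float("nan")
    sensitivity = _safe_ratio(tp, n_pos, "sensitivity")
    specificity = _safe_ratio(tn, n_neg, "specificity")
    precision = _safe_ratio(tp, tp + fp, "precision")

    if n_pos == 0 and tp + fp == 0:
        f1 = float("nan")
    elif tp == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)

    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined with a single class; reporting NaN", stacklevel=2)
        auc = float("nan")
    else:
        ranks = rankdata(p)  # average ranks implement the ties-count-1/2 rule
        auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    return MetricsReport(
        accuracy=float(accuracy),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        precision=float(precision),
        f1=float(f1),
        auc=float(auc),
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )
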