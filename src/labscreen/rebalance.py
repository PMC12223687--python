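"""Feature-space rebalancing of the augmented training set.

The combination augmentation produces windows whose density in feature space
mirrors visit frequency, not the phenomena of interest, and the label classes
are heavily imbalanced. Two corrections are applied:

1. *Region-stratified sampling*: project all rows onto the first principal
   component of the feature matrix, split the score range into R equal-width
   regions, and draw at most s rows per region — flattening the coverage of
   the dominant axis of variation (defaults R=100, s=1000, i.e. at most
   100,000 rows).
2. *Class balancing*: downsample the majority label to the minority count.

Both steps are seedable and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "PCProjection",
    "RegionSamplingPlan",
    "first_pc",
    "region_partition",
    "stratified_sample",
    "class_balance",
    "PCRegionResampler",
]


@dataclass(frozen=True)
class PCProjection:
    """First principal component of a feature matrix.

    ``component`` is the unit-norm loading vector with the sign convention
    that its largest-magnitude entry is positive (for reproducibility);
    ``scores`` are the centered projections; ``explained_variance`` is the
    sample variance (ddof=1) of the scores.
    """

    component: np.ndarray
    scores: np.ndarray
    explained_variance: float


@dataclass(frozen=True)
class RegionSamplingPlan:
    n_regions: int = 100
    per_region: int = 1000
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.per_region < 1:
            raise ValueError("per_region must be >= 1")


def first_pc(X) -> PCProjection:
    """Project rows onto the top eigenvector of the column-centered covariance."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D matrix with at least 2 rows and 1 column")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix must be finite")
    if np.allclose(X, X[0], atol=0.0):
        raise ValueError("zero-variance matrix has no principal direction")
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(X)[:, 0]
    comp = pca.components_[0]
    if comp[np.argmax(np.abs(comp))] < 0:
        comp = -comp
        scores = -scores
    ev = float(np.var(scores, ddof=1))
    return PCProjection(component=comp, scores=scores, explained_variance=ev)


def region_partition(scores, n_regions: int) -> np.ndarray:
    """Assign each score to one of ``n_regions`` equal-width intervals.

    Intervals span [min(scores), max(scores)]; the rightmost is closed. If
    all scores coincide, every row lands in region 0.
    """
    scores = np.asarray(scores, dtype=float)
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    lo, hi = scores.min(), scores.max()
    if lo == hi:
        return np.zeros(len(scores), dtype=int)
    idx = np.floor((scores - lo) / (hi - lo) * n_regions).astype(int)
    return np.clip(idx, 0, n_regions - 1)


def stratified_sample(
    groups: pd.DataFrame, regions: np.ndarray, plan: RegionSamplingPlan
) -> pd.DataFrame:
    """Draw up to ``plan.per_region`` rows from each nonempty region.

    Without replacement (the default), a region smaller than the quota
    contributes all of its rows; with replacement, exactly the quota is drawn
    from every nonempty region. Empty regions contribute nothing and are
    logged. Deterministic under ``plan.seed``.
    """
    regions = np.asarray(regions)
    if len(regions) != len(groups):
        raise ValueError("regions must align with the rows of groups")
    rng = np.random.default_rng(plan.seed)
    keep: list[np.ndarray] = []
    occupied = set(np.unique(regions).tolist())
    empty = plan.n_regions - len(occupied)
    if empty:
        logger.info("stratified_sample: %d of %d regions are empty", empty, plan.n_regions)
    for r in sorted(occupied):
        pos = np.flatnonzero(regions == r)
        if plan.with_replacement:
            keep.append(rng.choice(pos, size=plan.per_region, replace=True))
        elif len(pos) > plan.per_region:
            keep.append(rng.choice(pos, size=plan.per_region, replace=False))
        else:
            keep.append(pos)
    sel = np.concatenate(keep) if keep else np.array([], dtype=int)
    return groups.iloc[sel].reset_index(drop=True)


def class_balance(groups: pd.DataFrame, seed: int = 0, label_col: str = "label") -> pd.DataFrame:
    """Downsample the majority label uniformly to the minority count."""
    counts = groups[label_col].value_counts()
    if len(counts) < 2:
        raise ValueError("class_balance needs both label classes present")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for lab, grp in groups.groupby(label_col, sort=True):
        pos = np.arange(len(grp))
        if len(grp) > n_min:
            pos = np.sort(rng.choice(pos, size=n_min, replace=False))
        parts.append(grp.iloc[pos])
    return pd.concat(parts, ignore_index=True)


class PCRegionResampler:
    """Convenience wrapper chaining PC-region sampling and class balancing.

    Operates on a data-group frame with feature columns and a binary label
    column; ``resample`` returns a new frame. The two stages run in this
    order: coverage flattening first, then label equalization.
    """

    def __init__(
        self,
        n_regions: int = 100,
        per_region: int = 1000,
        balance_classes: bool = True,
        seed: int = 0,
        with_replacement: bool = False,
    ) -> None:
        self.n_regions = n_regions
        self.per_region = per_region
        self.balance_classes = balance_classes
        self.seed = seed
        self.with_replacement = with_replacement

    def resample(
        self, groups: pd.DataFrame, feature_cols: list[str], label_col: str = "label"
    ) -> pd.DataFrame:
        plan = RegionSamplingPlan(
            n_regions=self.n_regions,
            per_region=self.per_region,
            seed=self.seed,
            with_replacement=self.with_replacement,
        )
        proj = first_pc(groups[feature_cols].to_numpy(dtype=float))
        regions = region_partition(proj.scores, plan.n_regions)
        out = stratified_sample(groups, regions, plan)
        if self.balance_classes:
            out = class_balance(out, seed=self.seed + 1, label_col=label_col)
        return out
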