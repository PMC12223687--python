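"""Window construction and normalization for irregular lab series.

Hospital visits are aperiodic, so fixed-stride sliding windows under-use the
data. Instead, every chronologically ordered size-k subset of a patient's
series for one parameter becomes a window (the "combination" augmentation):
a series of n points yields C(n, k) windows, e.g. C(10, 4) = 210.

A window of k=4 points carries 8 numbers — 4 (value, date) pairs. The first 3
pairs are the features describing the recent trend; the 4th pair is the
target. The training label is whether the target point's *value* falls inside
the parameter's eligibility range (a date has no valid range). A stricter
mode additionally requires the 3rd value to be in range.

Values are min-max normalized with per-parameter minima/maxima fitted on the
training distribution only; dates become ``|date - screening_date| / N`` with
N a day-count normalization factor (default 365.25, i.e. offsets in years).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ranges import EligibilityRange

__all__ = [
    "FEATURE_COLUMNS",
    "SeriesWindow",
    "DataGroup",
    "NormalizationSpec",
    "label_value",
    "enumerate_windows",
    "normalize_window",
    "build_training_set",
    "build_inference_set",
    "build_evaluation_set",
    "dedupe_daily",
]

#: Feature layout of one row: 3 leading (normalized value, date offset) pairs.
FEATURE_COLUMNS = ["v1", "d1", "v2", "d2", "v3", "d3"]
GROUP_COLUMNS = ["patient_id", "parameter", *FEATURE_COLUMNS, "target_v", "target_d", "label"]


def label_value(value: float, range_: EligibilityRange) -> int:
    """1 if the value lies within the eligibility range, else 0."""
    if not np.isfinite(value):
        raise ValueError(f"value must be finite, got {value!r}")
    return int(range_.contains(float(value)))


@dataclass(frozen=True)
class SeriesWindow:
    """k chronologically ordered (value, date) points from one patient/parameter."""

    patient_id: str
    parameter: str
    points: tuple[tuple[float, date], ...]

    def __post_init__(self) -> None:
        dates = [d for _, d in self.points]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("window dates must be strictly increasing")


@dataclass(frozen=True)
class DataGroup:
    """One normalized training instance: 6 features, target pair, binary label."""

    patient_id: str
    parameter: str
    features: tuple[float, ...]  # v1, d1, v2, d2, v3, d3
    target_value: float  # normalized
    target_date_offset: float
    label: int


@dataclass
class NormalizationSpec:
    """Per-parameter min-max value scaling and date-offset scaling.

    Fit ``value_range`` on the training split only; inference/test values
    outside the training range map below 0 or above 1 (optionally clipped).
    """

    value_range: dict[str, tuple[float, float]]
    screening_date: date
    date_factor: float = 365.25
    clip: bool = False

    def __post_init__(self) -> None:
        if self.date_factor <= 0:
            raise ValueError("date_factor must be positive")
        for p, (lo, hi) in self.value_range.items():
            if not lo < hi:
                raise ValueError(f"degenerate value range for {p!r}: min == max")

    @classmethod
    def fit(
        cls,
        observations: pd.DataFrame,
        screening_date: date,
        date_factor: float = 365.25,
        clip: bool = False,
    ) -> "NormalizationSpec":
        """Fit per-parameter minima/maxima from a long-format extract."""
        vr = {}
        for p, grp in observations.groupby("parameter"):
            lo, hi = float(grp["value"].min()), float(grp["value"].max())
            if lo == hi:
                raise ValueError(f"all observed values equal for {p!r}; cannot min-max scale")
            vr[p] = (lo, hi)
        return cls(value_range=vr, screening_date=screening_date, date_factor=date_factor, clip=clip)

    def to_dict(self) -> dict:
        return {
            "value_range": {p: list(v) for p, v in self.value_range.items()},
            "screening_date": self.screening_date.isoformat(),
            "date_factor": self.date_factor,
            "clip": self.clip,
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "NormalizationSpec":
        return cls(
            value_range={p: (float(v[0]), float(v[1])) for p, v in raw["value_range"].items()},
            screening_date=date.fromisoformat(raw["screening_date"]),
            date_factor=float(raw.get("date_factor", 365.25)),
            clip=bool(raw.get("clip", False)),
        )

    def normalize_value(self, parameter: str, value):
        if parameter not in self.value_range:
            raise KeyError(f"no normalization fitted for parameter {parameter!r}")
        lo, hi = self.value_range[parameter]
        x = (np.asarray(value, dtype=float) - lo) / (hi - lo)
        if self.clip:
            x = np.clip(x, 0.0, 1.0)
        return x

    def denormalize_value(self, parameter: str, x):
        lo, hi = self.value_range[parameter]
        return np.asarray(x, dtype=float) * (hi - lo) + lo

    def normalize_date(self, d) -> float | np.ndarray:
        offs = np.abs(
            (pd.to_datetime(d) - pd.Timestamp(self.screening_date)) / pd.Timedelta(days=1)
        )
        return np.asarray(offs, dtype=float) / self.date_factor


def enumerate_windows(
    series: Sequence[tuple[float, date]],
    k: int = 4,
    patient_id: str = "",
    parameter: str = "",
) -> list[SeriesWindow]:
    """All chronologically ordered size-k subsets of a (value, date) series.

    The series must be pre-sorted by date with no duplicate dates; unsorted
    input raises. Returns C(n, k) windows; zero when n < k.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    dates = [d for _, d in series]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("series must be sorted by strictly increasing date")
    return [
        SeriesWindow(patient_id, parameter, tuple(combo))
        for combo in itertools.combinations(series, k)
    ]


def normalize_window(
    window: SeriesWindow,
    spec: NormalizationSpec,
    range_: EligibilityRange,
    strict_labels: bool = False,
) -> DataGroup:
    """Turn a raw window into a normalized, labeled data group.

    The label is computed from the *raw* target value (the window's last
    point); ``strict_labels`` additionally requires the 3rd point in range.
    """
    if window.parameter != range_.parameter:
        raise ValueError(
            f"window parameter {window.parameter!r} != range parameter {range_.parameter!r}"
        )
    vals = [v for v, _ in window.points]
    dts = [d for _, d in window.points]
    nv = [float(spec.normalize_value(window.parameter, v)) for v in vals]
    nd = [float(spec.normalize_date(d)) for d in dts]
    label = label_value(vals[-1], range_)
    if strict_labels:
        label = int(label and label_value(vals[-2], range_))
    feats = tuple(x for pair in zip(nv[:-1], nd[:-1]) for x in pair)
    return DataGroup(
        patient_id=window.patient_id,
        parameter=window.parameter,
        features=feats,
        target_value=nv[-1],
        target_date_offset=nd[-1],
        label=label,
    )


def dedupe_daily(observations: pd.DataFrame, how: str = "last") -> pd.DataFrame:
    """Collapse same-day duplicates per (patient, parameter) to one value.

    ``how='last'`` keeps the final measurement of the day; ``how='mean'``
    averages.
    """
    df = observations.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if how == "last":
        return df.drop_duplicates(subset=["patient_id", "parameter", "date"], keep="last")
    if how == "mean":
        return (
            df.groupby(["patient_id", "parameter", "date"], as_index=False, sort=False)["value"]
            .mean()
        )
    raise ValueError(f"unknown dedupe mode {how!r}")


def _series_groups(observations: pd.DataFrame) -> Iterable[tuple[str, str, pd.DataFrame]]:
    df = dedupe_daily(observations)
    df = df.sort_values(["patient_id", "parameter", "date"], kind="mergesort")
    for (pid, param), grp in df.groupby(["patient_id", "parameter"], sort=True):
        yield str(pid), str(param), grp


def build_training_set(
    observations: pd.DataFrame,
    ranges: Mapping[str, EligibilityRange],
    spec: NormalizationSpec,
    k: int = 4,
    strict_labels: bool = False,
) -> pd.DataFrame:
    """Augmented, normalized, labeled windows for every eligible series.

    Patients with fewer than k points for a parameter contribute nothing.
    Returns one frame with columns ``patient_id, parameter, v1, d1, v2, d2,
    v3, d3, target_v, target_d, label``.
    """
    parts = []
    for pid, param, grp in _series_groups(observations):
        n = len(grp)
        if n < k or param not in ranges:
            continue
        raw_v = grp["value"].to_numpy(dtype=float)
        norm_v = np.asarray(spec.normalize_value(param, raw_v), dtype=float)
        norm_d = np.asarray(spec.normalize_date(grp["date"].to_numpy()), dtype=float)
        idx = np.array(list(itertools.combinations(range(n), k)), dtype=int)
        rng = ranges[param]
        target_raw = raw_v[idx[:, -1]]
        labels = np.fromiter((label_value(v, rng) for v in target_raw), dtype=int)
        if strict_labels:
            third_raw = raw_v[idx[:, -2]]
            labels &= np.fromiter((label_value(v, rng) for v in third_raw), dtype=int)
        data = {"patient_id": pid, "parameter": param}
        for j in range(k - 1):
            data[f"v{j + 1}"] = norm_v[idx[:, j]]
            data[f"d{j + 1}"] = norm_d[idx[:, j]]
        data["target_v"] = norm_v[idx[:, -1]]
        data["target_d"] = norm_d[idx[:, -1]]
        data["label"] = labels
        parts.append(pd.DataFrame(data))
    if not parts:
        return pd.DataFrame(columns=GROUP_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def _select_window_obs(
    observations: pd.DataFrame, screening_window: tuple[date, date]
) -> pd.DataFrame:
    lo, hi = screening_window
    if lo >= hi:
        raise ValueError("screening_window must be a nonempty interval")
    df = dedupe_daily(observations)
    mask = (pd.to_datetime(df["date"]) >= pd.Timestamp(lo)) & (
        pd.to_datetime(df["date"]) <= pd.Timestamp(hi)
    )
    return df.loc[mask]


def build_inference_set(
    observations: pd.DataFrame,
    spec: NormalizationSpec,
    screening_window: tuple[date, date],
    m_last: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature rows for scoring: the last ``m_last`` points per series.

    For each (patient, parameter) with at least ``m_last`` observations inside
    the screening window, emit one normalized feature row from the most recent
    ``m_last`` points. Returns ``(features, not_scorable)``; the second frame
    lists (patient, parameter, n_points) for series with insufficient history
    — reported, never silently dropped.
    """
    sel = _select_window_obs(observations, screening_window)
    rows, missing = [], []
    for pid, param, grp in _series_groups(sel):
        if param not in spec.value_range:
            continue
        if len(grp) < m_last:
            missing.append({"patient_id": pid, "parameter": param, "n_points": len(grp)})
            continue
        tail = grp.iloc[-m_last:]
        nv = np.asarray(spec.normalize_value(param, tail["value"].to_numpy(dtype=float)))
        nd = np.asarray(spec.normalize_date(tail["date"].to_numpy()))
        row: dict = {"patient_id": pid, "parameter": param}
        for j in range(m_last):
            row[f"v{j + 1}"] = float(nv[j])
            row[f"d{j + 1}"] = float(nd[j])
        rows.append(row)
    feat_cols = ["patient_id", "parameter"] + [
        f"{c}{j + 1}" for j in range(m_last) for c in ("v", "d")
    ]
    features = pd.DataFrame(rows, columns=feat_cols)
    not_scorable = pd.DataFrame(missing, columns=["patient_id", "parameter", "n_points"])
    return features, not_scorable


def build_evaluation_set(
    observations: pd.DataFrame,
    ranges: Mapping[str, EligibilityRange],
    spec: NormalizationSpec,
    screening_window: tuple[date, date],
    m_last: int = 3,
) -> pd.DataFrame:
    """Application-test rows with ground truth for back-testing a screen.

    For each (patient, parameter) with at least ``m_last + 1`` points in the
    window, the features come from the ``m_last`` points preceding the most
    recent one, and ``label`` is whether the most recent (held-out) value lies
    in the eligibility range — the quantity a prescreen tries to predict.
    """
    sel = _select_window_obs(observations, screening_window)
    rows = []
    for pid, param, grp in _series_groups(sel):
        if param not in ranges or param not in spec.value_range:
            continue
        if len(grp) < m_last + 1:
            continue
        tail = grp.iloc[-(m_last + 1):]
        feats, target = tail.iloc[:-1], tail.iloc[-1]
        nv = np.asarray(spec.normalize_value(param, feats["value"].to_numpy(dtype=float)))
        nd = np.asarray(spec.normalize_date(feats["date"].to_numpy()))
        row: dict = {"patient_id": pid, "parameter": param}
        for j in range(m_last):
            row[f"v{j + 1}"] = float(nv[j])
            row[f"d{j + 1}"] = float(nd[j])
        row["label"] = label_value(float(target["value"]), ranges[param])
        rows.append(row)
    cols = ["patient_id", "parameter"] + [
        f"{c}{j + 1}" for j in range(m_last) for c in ("v", "d")
    ] + ["label"]
    return pd.DataFrame(rows, columns=cols)
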