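"""Windowing, normalization and labeling of irregular lab series."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_series
from labscreen import (
    EligibilityRange,
    NormalizationSpec,
    build_evaluation_set,
    build_inference_set,
    build_training_set,
    enumerate_windows,
    label_value,
    normalize_window,
)
from labscreen.preprocess import FEATURE_COLUMNS, SeriesWindow, dedupe_daily

HGB = EligibilityRange("hemoglobin", 13.0, 18.0)
CRE = EligibilityRange("creatinine", 0.7, 1.2)


def obs_frame(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "parameter", "value", "date"])
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def simple_spec(**kw):
    defaults = dict(
        value_range={"hemoglobin": (10.0, 20.0), "creatinine": (0.4, 2.0)},
        screening_date=date(2019, 1, 1),
        date_factor=365.25,
    )
    defaults.update(kw)
    return NormalizationSpec(**defaults)


class TestLabelValue:
    @pytest.mark.parametrize(
        "value,range_,expected",
        [
            (15.0, HGB, 1),
            (12.9, HGB, 0),
            (18.0, HGB, 1),  # inclusive upper bound
            (0.7, CRE, 1),  # inclusive lower bound
            (1.21, CRE, 0),
        ],
    )
    def test_range_membership(self, value, range_, expected):
        assert label_value(value, range_) == expected

    def test_exclusive_bounds(self):
        r = EligibilityRange("x", 0.0, 1.0, inclusive_low=False, inclusive_high=False)
        assert label_value(0.0, r) == 0
        assert label_value(1.0, r) == 0
        assert label_value(0.5, r) == 1

    def test_nonfinite_value_rejected(self):
        with pytest.raises(ValueError):
            label_value(float("nan"), HGB)


def brute_force_subsets(seq, k):
    """Independent recursive k-subset enumeration (order-preserving)."""
    if k == 0:
        return [()]
    if len(seq) < k:
        return []
    head, tail = seq[0], seq[1:]
    with_head = [(head, *rest) for rest in brute_force_subsets(tail, k - 1)]
    return with_head + brute_force_subsets(tail, k)


class TestEnumerateWindows:
    @pytest.mark.parametrize("n,k", [(n, k) for n in range(2, 13) for k in range(2, n + 1)])
    def test_count_is_n_choose_k(self, n, k):
        series = make_series(range(n))
        assert len(enumerate_windows(series, k)) == math.comb(n, k)

    def test_ten_points_give_210_windows(self):
        assert len(enumerate_windows(make_series(range(10)), 4)) == 210

    def test_n_equals_k_returns_the_series_itself(self):
        series = make_series([1, 2, 3, 4])
        (w,) = enumerate_windows(series, 4)
        assert w.points == tuple(series)

    def test_below_window_size_yields_nothing(self):
        assert enumerate_windows(make_series([1, 2, 3]), 4) == []

    def test_matches_recursive_enumeration_oracle(self):
        series = make_series([5, 1, 4, 2, 3, 6])
        got = {w.points for w in enumerate_windows(series, 4)}
        expected = set(brute_force_subsets(tuple(series), 4))
        assert got == expected
        assert len(got) == 15

    def test_windows_preserve_chronology(self):
        series = make_series(range(8))
        for w in enumerate_windows(series, 4):
            dates = [d for _, d in w.points]
            assert all(a < b for a, b in zip(dates, dates[1:]))

    def test_unsorted_input_rejected(self):
        series = make_series([1, 2, 3, 4, 5])
        series[0], series[1] = series[1], series[0]
        with pytest.raises(ValueError):
            enumerate_windows(series, 4)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            enumerate_windows(make_series([1, 2, 3]), 1)


class TestNormalizeWindow:
    def window(self, values, dates=None):
        series = make_series(values) if dates is None else list(zip(values, dates))
        return SeriesWindow("P1", "hemoglobin", tuple(series))

    def test_value_endpoints_map_to_unit_interval_ends(self):
        spec = simple_spec()
        w = self.window([10.0, 20.0, 15.0, 14.0])
        g = normalize_window(w, spec, HGB)
        assert g.features[0] == pytest.approx(0.0)  # value_min
        assert g.features[2] == pytest.approx(1.0)  # value_max

    def test_screening_date_offset_is_zero(self):
        spec = simple_spec()
        dates = [date(2018, 1, 1), date(2018, 3, 1), date(2018, 6, 1), date(2019, 1, 1)]
        g = normalize_window(self.window([15, 15, 15, 15], dates), spec, HGB)
        assert g.target_date_offset == pytest.approx(0.0)
        assert g.features[1] == pytest.approx(365 / 365.25)

    @pytest.mark.parametrize("target,expected", [(15.0, 1), (12.0, 0)])
    def test_label_follows_target_point_value(self, target, expected):
        g = normalize_window(self.window([15.0, 15.0, 15.0, target]), simple_spec(), HGB)
        assert g.label == expected

    def test_strict_mode_requires_third_point_too(self):
        w = self.window([15.0, 15.0, 12.0, 15.0])  # 3rd out, 4th in
        assert normalize_window(w, simple_spec(), HGB).label == 1
        assert normalize_window(w, simple_spec(), HGB, strict_labels=True).label == 0

    def test_parameter_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalize_window(self.window([1, 1, 1, 1]), simple_spec(), CRE)

    def test_degenerate_value_range_rejected(self):
        with pytest.raises(ValueError):
            NormalizationSpec(value_range={"x": (5.0, 5.0)}, screening_date=date(2019, 1, 1))

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=10.0, max_value=20.0))
    def test_normalization_invertible_on_training_range(self, v):
        spec = simple_spec()
        x = spec.normalize_value("hemoglobin", v)
        assert float(spec.denormalize_value("hemoglobin", x)) == pytest.approx(v, abs=1e-9)


class TestBuildTrainingSet:
    def test_single_patient_ten_points_gives_210_groups(self):
        rows = [("P1", "hemoglobin", 15.0 + i * 0.1, f"2015-{i + 1:02d}-01") for i in range(10)]
        groups = build_training_set(obs_frame(rows), {"hemoglobin": HGB}, simple_spec())
        assert len(groups) == 210
        # each group holds 8 numeric values: 6 features + target value/date pair
        assert groups[FEATURE_COLUMNS + ["target_v", "target_d"]].notna().all().all()

    def test_three_points_give_nothing(self):
        rows = [("P1", "hemoglobin", 15.0, f"2015-0{i + 1}-01") for i in range(3)]
        groups = build_training_set(obs_frame(rows), {"hemoglobin": HGB}, simple_spec())
        assert len(groups) == 0

    def test_counts_add_over_patients(self):
        rows = [("A", "hemoglobin", 15.0, f"2015-{i + 1:02d}-01") for i in range(5)]
        rows += [("B", "hemoglobin", 15.0, f"2015-{i + 1:02d}-01") for i in range(6)]
        groups = build_training_set(obs_frame(rows), {"hemoglobin": HGB}, simple_spec())
        assert len(groups) == math.comb(5, 4) + math.comb(6, 4) == 20

    def test_label_counts_match_direct_target_labeling(self, small_cohort, ranges):
        spec = NormalizationSpec.fit(small_cohort, screening_date=date(2019, 1, 1))
        groups = build_training_set(small_cohort, ranges, spec)
        for (pid, param), grp in small_cohort.groupby(["patient_id", "parameter"]):
            sub = groups[(groups["patient_id"] == pid) & (groups["parameter"] == param)]
            if sub.empty:
                continue
            series = grp.sort_values("date")
            vals = series["value"].to_numpy()
            n = len(vals)
            # direct oracle: each point v_i is the target of C(i, 3) windows
            expected_pos = sum(
                math.comb(i, 3) * label_value(vals[i], ranges[param]) for i in range(3, n)
            )
            assert sub["label"].sum() == expected_pos

    def test_dedupe_keeps_last_same_day_value(self):
        rows = [
            ("P1", "hemoglobin", 14.0, "2015-01-01"),
            ("P1", "hemoglobin", 16.0, "2015-01-01"),
        ]
        out = dedupe_daily(obs_frame(rows))
        assert len(out) == 1 and out["value"].iloc[0] == 16.0
        out_mean = dedupe_daily(obs_frame(rows), how="mean")
        assert out_mean["value"].iloc[0] == pytest.approx(15.0)


class TestInferenceAndEvaluationSets:
    WINDOW = (date(2015, 1, 1), date(2019, 1, 1))

    def rows(self, n, pid="P1"):
        return [(pid, "hemoglobin", 14.0 + 0.1 * i, f"2015-{i + 1:02d}-01") for i in range(n)]

    def test_exactly_three_points_scorable(self):
        feats, missing = build_inference_set(obs_frame(self.rows(3)), simple_spec(), self.WINDOW)
        assert len(feats) == 1 and len(missing) == 0

    def test_two_points_not_scorable_but_reported(self):
        feats, missing = build_inference_set(obs_frame(self.rows(2)), simple_spec(), self.WINDOW)
        assert len(feats) == 0
        assert missing.iloc[0]["n_points"] == 2

    def test_seven_points_use_only_the_last_three(self):
        spec = simple_spec()
        obs = obs_frame(self.rows(7))
        feats, _ = build_inference_set(obs, spec, self.WINDOW)
        manual = obs.sort_values("date").iloc[-3:]
        expected_v = spec.normalize_value("hemoglobin", manual["value"].to_numpy())
        assert feats[["v1", "v2", "v3"]].to_numpy()[0] == pytest.approx(expected_v)

    def test_evaluation_set_holds_out_latest_point_as_truth(self):
        spec = simple_spec()
        rows = self.rows(4)
        rows[-1] = ("P1", "hemoglobin", 12.0, "2015-04-01")  # latest value out of range
        ev = build_evaluation_set(obs_frame(rows), {"hemoglobin": HGB}, spec, self.WINDOW)
        assert len(ev) == 1
        assert ev["label"].iloc[0] == 0
        # features come from the first three points only
        expected_v = spec.normalize_value("hemoglobin", np.array([14.0, 14.1, 14.2]))
        assert ev[["v1", "v2", "v3"]].to_numpy()[0] == pytest.approx(expected_v)

    def test_empty_screening_window_rejected(self):
        with pytest.raises(ValueError):
            build_inference_set(
                obs_frame(self.rows(3)), simple_spec(), (date(2019, 1, 1), date(2015, 1, 1))
            )
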