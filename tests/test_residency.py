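import datetime as dt

import numpy as np
import pandas as pd
import pytest

from tidegate.config import StudyConfig
from tidegate.residency import (
    bouts,
    build_presence,
    categorize_residency,
    monthly_receiver_profile,
    remaining_proportion,
    residency_indices,
    roaming_index,
)


def presence_from_spec(config, spec):
    """Build presence from {tag: {day_offset: receiver set}} shorthand."""
    rows = []
    base = pd.Timestamp(config.study_start)
    for tag, days in spec.items():
        for off, receivers in days.items():
            day = base + pd.Timedelta(days=off)
            for k, r in enumerate(receivers):
                rows.append((day + pd.Timedelta(hours=9 + k), tag, r))
    det = pd.DataFrame(
        {
            "timestamp": pd.to_datetime([r[0] for r in rows]),
            "tag_id": [r[1] for r in rows],
            "receiver_id": [r[2] for r in rows],
        }
    )
    return build_presence(det, config)


class TestBuildPresence:
    def test_single_detection(self, config, det_factory):
        det = det_factory([("2020-01-05 10:00:00", "A", "R2")])
        p = build_presence(det, config)
        day = pd.Timestamp("2020-01-05")
        assert p.presence.loc[day, "A"]
        assert p.receivers_on("A", day) == frozenset({"R2"})
        assert p.presence["A"].sum() == 1

    def test_no_detections_all_false(self, config, det_factory, tags):
        det = det_factory([]).iloc[:0]
        p = build_presence(det, config, tags=tags)
        assert not p.presence.to_numpy().any()
        assert list(p.presence.columns) == ["A", "B"]

    def test_midnight_boundary_two_days(self, config, det_factory):
        det = det_factory(
            [("2020-01-05 23:59:00", "A", "R1"), ("2020-01-06 00:01:00", "A", "R1")]
        )
        p = build_presence(det, config)
        assert p.presence["A"].sum() == 2

    def test_day_axis_spans_full_window(self, config, det_factory):
        det = det_factory([("2020-01-05 10:00:00", "A", "R2")])
        p = build_presence(det, config)
        assert p.presence.index[0] == pd.Timestamp(config.study_start)
        assert p.presence.index[-1] == pd.Timestamp(config.study_end)


class TestResidencyIndices:
    def test_detected_every_spanned_day_max_is_one(self, config):
        p = presence_from_spec(config, {"A": {d: ["R1"] for d in range(10, 20)}})
        (rec,) = residency_indices(p, 5)
        assert rec.max_residency == 1.0
        assert rec.days_detected == 10

    def test_two_days_ten_day_span(self, config):
        p = presence_from_spec(config, {"A": {0: ["R1"], 9: ["R1"]}})
        (rec,) = residency_indices(p, 5)
        assert rec.max_residency == pytest.approx(2 / 10)

    def test_min_uses_fixed_study_duration(self, full_config):
        spec = {"A": {d: ["R1"] for d in range(100)}}
        p = presence_from_spec(full_config, spec)
        (rec,) = residency_indices(p, 5)
        assert rec.min_residency == pytest.approx(100 / 497)

    def test_zero_detection_tags_omitted(self, config, det_factory, tags):
        det = det_factory([("2020-01-05 10:00:00", "A", "R1")])
        p = build_presence(det, config, tags=tags)
        recs = residency_indices(p, 5)
        assert [r.tag_id for r in recs] == ["A"]

    def test_min_le_max_always(self, config):
        rng = np.random.default_rng(0)
        spec = {
            f"T{i}": {
                int(d): ["R1"]
                for d in rng.choice(90, size=rng.integers(1, 40), replace=False)
            }
            for i in range(8)
        }
        p = presence_from_spec(config, spec)
        for rec in residency_indices(p, 5):
            assert rec.min_residency <= rec.max_residency + 1e-12


class TestRoaming:
    def test_single_receiver_gives_point_two(self, config):
        p = presence_from_spec(config, {"A": {d: ["R1"] for d in range(7)}})
        assert roaming_index(p, 5)["A"] == pytest.approx(0.2)

    def test_all_five_receivers_gives_one(self, config):
        p = presence_from_spec(
            config, {"A": {d: ["R1", "R2", "R3", "R4", "R5"] for d in range(4)}}
        )
        assert roaming_index(p, 5)["A"] == pytest.approx(1.0)

    def test_two_then_three_receivers_half(self, config):
        p = presence_from_spec(
            config, {"A": {0: ["R1", "R2"], 1: ["R1", "R2", "R3"]}}
        )
        assert roaming_index(p, 5)["A"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_enumeration(self, config, seed):
        rng = np.random.default_rng(seed)
        receivers = ["R1", "R2", "R3", "R4", "R5"]
        spec = {
            "A": {
                d: list(rng.choice(receivers, size=rng.integers(1, 6), replace=False))
                for d in range(rng.integers(1, 10))
            }
        }
        p = presence_from_spec(config, spec)
        oracle = np.mean([len(set(v)) / 5 for v in spec["A"].values()])
        assert roaming_index(p, 5)["A"] == pytest.approx(oracle)


class TestCategories:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.05, "vagrant"),
            (0.1, "short-term"),
            (0.5, "short-term"),
            (0.51, "long-term"),
            (0.69, "long-term"),
        ],
    )
    def test_thresholds(self, value, expected):
        assert categorize_residency(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_residency(1.2)


class TestBouts:
    def test_run_length_encoding(self, config):
        # presence 1,1,0,0,0,1 -> presence bouts {2,1}, absence {3}
        p = presence_from_spec(config, {"A": {0: ["R1"], 1: ["R1"], 5: ["R1"]}})
        b = bouts(p)["A"]
        assert b["presence"] == [2, 1]
        assert b["absence"] == [3]

    def test_all_present_single_bout(self, config):
        p = presence_from_spec(config, {"A": {d: ["R1"] for d in range(5)}})
        b = bouts(p)["A"]
        assert b["presence"] == [5] and b["absence"] == []

    def test_single_day(self, config):
        p = presence_from_spec(config, {"A": {3: ["R1"]}})
        assert bouts(p)["A"] == {"presence": [1], "absence": []}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bout_lengths_sum_to_span(self, config, seed):
        rng = np.random.default_rng(seed)
        days = sorted(rng.choice(80, size=rng.integers(1, 30), replace=False))
        p = presence_from_spec(config, {"A": {int(d): ["R1"] for d in days}})
        b = bouts(p)["A"]
        span = days[-1] - days[0] + 1
        assert sum(b["presence"]) + sum(b["absence"]) == span


class TestRemainingProportion:
    def test_simple_ratio(self, config):
        spec = {f"T{i}": {0: ["R1"], 50: ["R1"]} for i in range(10)}
        for i in range(4):
            spec[f"T{i}"][10] = ["R1"]
        p = presence_from_spec(config, spec)
        rp = remaining_proportion(p)
        day10 = pd.Timestamp(config.study_start) + pd.Timedelta(days=10)
        assert rp.loc[day10, "proportion"] == pytest.approx(0.4)

    def test_tag_leaves_denominator_after_last_detection(self, config):
        p = presence_from_spec(config, {"A": {0: ["R1"], 5: ["R1"]}, "B": {0: ["R1"], 60: ["R1"]}})
        rp = remaining_proportion(p)
        base = pd.Timestamp(config.study_start)
        assert rp.loc[base + pd.Timedelta(days=5), "n_remaining"] == 2
        assert rp.loc[base + pd.Timedelta(days=6), "n_remaining"] == 1

    def test_empty_denominator_gives_missing(self, config):
        p = presence_from_spec(config, {"A": {0: ["R1"]}})
        rp = remaining_proportion(p)
        later = pd.Timestamp(config.study_start) + pd.Timedelta(days=30)
        assert rp.loc[later, "n_remaining"] == 0
        assert np.isnan(rp.loc[later, "proportion"])

    def test_invariant_to_post_departure_empty_days(self, det_factory):
        det = det_factory(
            [("2020-01-05 10:00:00", "A", "R1"), ("2020-01-20 10:00:00", "A", "R1")]
        )
        short = StudyConfig(dt.date(2020, 1, 1), dt.date(2020, 1, 25), 0.0)
        long = StudyConfig(dt.date(2020, 1, 1), dt.date(2020, 3, 25), 0.0)
        a = remaining_proportion(build_presence(det, short))
        b = remaining_proportion(build_presence(det, long))
        overlap = a.index
        pd.testing.assert_frame_equal(a, b.loc[overlap])


class TestMonthlyReceiverProfile:
    def test_faithful_single_tag(self, config):
        p = presence_from_spec(config, {"A": {d: ["R1"] for d in range(91)}})
        prof = monthly_receiver_profile(p)
        assert np.allclose(prof["R1"].dropna(), 1.0)

    def test_month_without_detections_zero(self, config):
        # tag detected in January and March; remains in denominator in Feb
        spec = {"A": {d: ["R1"] for d in range(0, 25)}}
        spec["A"][80] = ["R1"]
        p = presence_from_spec(config, spec)
        prof = monthly_receiver_profile(p)
        assert prof.loc[2, "R1"] == pytest.approx(0.0)
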