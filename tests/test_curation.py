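import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tidegate.curation import (
    curate,
    drop_tagging_window,
    exclude_nonrepresentative_tags,
    flag_stationary_tags,
    remove_collisions,
    remove_daily_singletons,
)


def collision_oracle(det, window):
    """Brute-force pairwise scan: the spec's reference for the proxy rule."""
    det = det.drop_duplicates(subset=["timestamp", "tag_id", "receiver_id"])
    keep = []
    for i, a in det.iterrows():
        hit = False
        for j, b in det.iterrows():
            if i == j or a.receiver_id != b.receiver_id or a.tag_id == b.tag_id:
                continue
            if abs((a.timestamp - b.timestamp).total_seconds()) < window:
                hit = True
                break
        keep.append(not hit)
    return det[keep].sort_values("timestamp", kind="mergesort").reset_index(drop=True)


class TestCollisions:
    def test_same_second_different_tags_removed(self, det_factory):
        det = det_factory(
            [("2020-01-02 10:00:00", "A", "R1"), ("2020-01-02 10:00:00", "B", "R1")]
        )
        assert len(remove_collisions(det, window=1.0)) == 0

    def test_different_receivers_kept(self, det_factory):
        det = det_factory(
            [("2020-01-02 10:00:00", "A", "R1"), ("2020-01-02 10:00:00", "B", "R2")]
        )
        assert len(remove_collisions(det, window=1.0)) == 2

    def test_window_zero_only_exact_duplicates(self, det_factory):
        det = det_factory(
            [
                ("2020-01-02 10:00:00", "A", "R1"),
                ("2020-01-02 10:00:00", "A", "R1"),  # exact duplicate
                ("2020-01-02 10:00:00", "B", "R1"),  # simultaneous other tag
            ]
        )
        out = remove_collisions(det, window=0.0)
        assert len(out) == 2 and set(out["tag_id"]) == {"A", "B"}

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 30),  # seconds offset
                st.sampled_from(["A", "B", "C"]),
                st.sampled_from(["R1", "R2"]),
            ),
            min_size=1,
            max_size=12,
        ),
        window=st.sampled_from([1.0, 2.0, 5.0]),
    )
    def test_matches_bruteforce_oracle(self, data, window):
        det = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(
                    [f"2020-01-02 10:00:{s:02d}" for s, _, _ in data]
                ),
                "tag_id": [t for _, t, _ in data],
                "receiver_id": [r for _, _, r in data],
            }
        ).sort_values("timestamp", kind="mergesort").reset_index(drop=True)
        got = remove_collisions(det, window=window)
        want = collision_oracle(det, window)
        pd.testing.assert_frame_equal(got, want)


class TestDailySingletons:
    def test_lone_hit_removed_group_kept(self, config, det_factory):
        det = det_factory(
            [("2020-01-02 10:00:00", "A", "R1")]
            + [(f"2020-01-02 1{i}:00:00", "A", "R2") for i in range(5)]
        )
        out = remove_daily_singletons(det, config)
        assert set(out["receiver_id"]) == {"R2"} and len(out) == 5

    def test_pair_is_kept(self, config, det_factory):
        det = det_factory(
            [("2020-01-02 10:00:00", "A", "R1"), ("2020-01-02 11:00:00", "A", "R1")]
        )
        assert len(remove_daily_singletons(det, config)) == 2

    def test_empty_table(self, config, det_factory):
        det = det_factory([]).iloc[:0]
        assert remove_daily_singletons(det, config).empty


class TestTaggingWindowAndExclusions:
    def test_tagging_days_dropped(self, config, det_factory):
        det = det_factory(
            [
                ("2020-01-01 10:00:00", "A", "R1"),
                ("2020-01-02 10:00:00", "A", "R1"),
            ]
        )
        out = drop_tagging_window(det, [dt.date(2020, 1, 1)], config)
        assert len(out) == 1 and out["timestamp"].dt.day.iloc[0] == 2

    def test_empty_tagging_set_is_identity(self, config, det_factory):
        det = det_factory([("2020-01-05 10:00:00", "A", "R1")])
        pd.testing.assert_frame_equal(drop_tagging_window(det, [], config), det)

    def test_first_days_only_tag_excluded(self, config, det_factory):
        det = det_factory(
            [
                ("2020-01-01 10:00:00", "X", "R1"),  # day 0
                ("2020-01-02 10:00:00", "X", "R1"),  # day 1
                ("2020-01-03 10:00:00", "Y", "R1"),  # day 2
                ("2020-02-09 10:00:00", "Y", "R1"),  # day 39
            ]
        )
        out, report = exclude_nonrepresentative_tags(det, config, horizon_days=5)
        assert set(out["tag_id"]) == {"Y"}
        assert [t for t, _ in report.excluded_tags] == ["X"]

    def test_all_tags_beyond_horizon_identity(self, config, det_factory):
        det = det_factory([("2020-02-01 10:00:00", "A", "R1")])
        out, report = exclude_nonrepresentative_tags(det, config)
        assert len(out) == 1 and report.excluded_tags == []


class TestStationaryTags:
    def _daily(self, det_factory, tag, receiver, days, start="2020-01-01"):
        base = pd.Timestamp(start)
        rows = []
        for d in range(days):
            day = base + pd.Timedelta(days=d)
            rows += [(day + pd.Timedelta(hours=h), tag, receiver) for h in (9, 15)]
        return det_factory(rows)

    def test_long_single_receiver_run_flagged(self, config, det_factory):
        det = self._daily(det_factory, "S", "R3", 60)
        assert flag_stationary_tags(det, config, min_span_days=30) == ["S"]

    def test_alternating_receivers_not_flagged(self, config, det_factory):
        base = pd.Timestamp("2020-01-01")
        rows = []
        for d in range(60):
            day = base + pd.Timedelta(days=d)
            r = "R1" if d % 2 == 0 else "R2"
            rows += [(day + pd.Timedelta(hours=h), "S", r) for h in (9, 15)]
        det = det_factory(rows)
        assert flag_stationary_tags(det, config, min_span_days=30) == []

    def test_short_history_not_flagged(self, config, det_factory):
        det = self._daily(det_factory, "S", "R3", 10)
        assert flag_stationary_tags(det, config, min_span_days=30) == []


class TestFullChain:
    def _random_det(self, det_factory, seed):
        rng = np.random.default_rng(seed)
        rows = []
        base = pd.Timestamp("2020-01-01")
        for _ in range(120):
            t = base + pd.Timedelta(seconds=int(rng.integers(0, 40 * 86400)))
            rows.append(
                (t, rng.choice(["A", "B", "C"]), rng.choice(["R1", "R2", "R3"]))
            )
        return det_factory(rows)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotent(self, config, det_factory, seed):
        det = self._random_det(det_factory, seed)
        once, _ = curate(det, config)
        twice, rep2 = curate(once, config)
        pd.testing.assert_frame_equal(twice, once)
        assert rep2.n_collision_removed == 0 and rep2.n_singleton_removed == 0

    @pytest.mark.parametrize("seed", [0, 3])
    def test_output_subset_of_input(self, config, det_factory, seed):
        det = self._random_det(det_factory, seed)
        out, _ = curate(det, config)
        merged = out.merge(det, on=list(det.columns), how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_pipeline_enforces_collisions_before_singletons(
        self, config, det_factory
    ):
        # A and B collide at R1; B has one later hit at R1 the same day.
        # collisions-first leaves B's lone hit, which the singleton filter
        # then removes -> empty.  singletons-first would instead remove A
        # (a singleton) and keep B's pair untouched by the collision rule.
        det = det_factory(
            [
                ("2020-01-02 10:00:00", "A", "R1"),
                ("2020-01-02 10:00:00", "B", "R1"),
                ("2020-01-02 15:00:00", "B", "R1"),
            ]
        )
        out, report = curate(det, config)
        assert out.empty
        swapped = remove_collisions(remove_daily_singletons(det, config), 1.0)
        assert not swapped.empty  # the order genuinely matters

    def test_report_counts_sum_consistent(self, config, det_factory):
        det = self._random_det(det_factory, 5)
        out, report = curate(det, config)
        report.validate()
        assert report.n_output == len(out)
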