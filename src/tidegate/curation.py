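"""Data-quality screening of raw acoustic detections.

Receivers cannot log true code collisions, so near-simultaneous detections of
different tags at one receiver are the operational proxy for them.  The full
chain, in a fixed order (any other order changes the daily-singleton counts):

1. collision proxy + exact-duplicate removal
2. daily singletons per (tag, receiver, local day)
3. tagging-window days
4. tags only seen within the first days of the study (non-representative)

A separate inspection step flags tags that sit at a single receiver for a long
unbroken run of days (suggesting tag loss/expulsion); flagged tags are
reported, and excluded only when asked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig

__all__ = [
    "CurationReport",
    "remove_collisions",
    "remove_daily_singletons",
    "drop_tagging_window",
    "exclude_nonrepresentative_tags",
    "flag_stationary_tags",
    "curate",
]


@dataclass
class CurationReport:
    n_input: int = 0
    n_collision_removed: int = 0
    n_singleton_removed: int = 0
    n_tagging_window_removed: int = 0
    n_nonrepresentative_removed: int = 0
    n_output: int = 0
    excluded_tags: list = field(default_factory=list)  # (tag_id, reason)
    stationary_tags: list = field(default_factory=list)

    def validate(self) -> None:
        counts = [
            self.n_collision_removed,
            self.n_singleton_removed,
            self.n_tagging_window_removed,
            self.n_nonrepresentative_removed,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("negative removal count")
        if self.n_input - sum(counts) != self.n_output:
            raise ValueError("curation counts are not sum-consistent with output size")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_collision_removed": self.n_collision_removed,
            "n_singleton_removed": self.n_singleton_removed,
            "n_tagging_window_removed": self.n_tagging_window_removed,
            "n_nonrepresentative_removed": self.n_nonrepresentative_removed,
            "n_output": self.n_output,
            "excluded_tags": list(self.excluded_tags),
            "stationary_tags": list(self.stationary_tags),
        }


def remove_collisions(det: pd.DataFrame, window: float = 1.0) -> pd.DataFrame:
    """Remove near-simultaneous multi-tag detections at one receiver.

    A detection is removed when another detection of a *different* tag exists
    at the *same* receiver with time difference strictly less than ``window``
    seconds.  ``window=0`` therefore removes nothing under this rule.  Exact
    duplicate rows (same tag, receiver and timestamp) are collapsed to one
    copy in the same pass.
    """
    if det.empty:
        return det.reset_index(drop=True)
    det = det.drop_duplicates(subset=["timestamp", "tag_id", "receiver_id"])
    det = det.reset_index(drop=True)
    order = det.index.to_numpy()  # preserve the incoming row order for ties
    det = det.sort_values(["receiver_id", "timestamp"], kind="mergesort")
    orig = order[det.index.to_numpy()]
    det = det.reset_index(drop=True)
    if window <= 0:
        return det.iloc[np.argsort(orig, kind="stable")].reset_index(drop=True)
    drop = np.zeros(len(det), dtype=bool)
    for _, grp in det.groupby("receiver_id", sort=False):
        t = grp["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64) / 1e9
        tags = grp["tag_id"].to_numpy()
        idxs = grp.index.to_numpy()
        n = len(grp)
        j0 = 0
        for i in range(n):
            while t[i] - t[j0] >= window:
                j0 += 1
            for j in range(j0, n):
                if j == i:
                    continue
                if t[j] - t[i] >= window:
                    break
                if tags[j] != tags[i]:
                    drop[idxs[i]] = True
                    break
    keep = np.flatnonzero(~drop)
    keep = keep[np.argsort(orig[keep], kind="stable")]
    return det.iloc[keep].reset_index(drop=True)


def remove_daily_singletons(det: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Drop lone detections per (tag, receiver, local day); groups >=2 stay whole."""
    if det.empty:
        return det.reset_index(drop=True)
    day = config.local_day(det["timestamp"])
    sizes = det.groupby([det["tag_id"], det["receiver_id"], day])["timestamp"].transform(
        "size"
    )
    out = det[sizes >= 2]
    return out.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def drop_tagging_window(det: pd.DataFrame, tagging_days, config: StudyConfig) -> pd.DataFrame:
    """Remove all detections whose local day is in ``tagging_days``."""
    if det.empty or not len(tagging_days):
        return det.reset_index(drop=True)
    days = {pd.Timestamp(d).normalize() for d in tagging_days}
    day = config.local_day(det["timestamp"])
    return det[~day.isin(days)].reset_index(drop=True)


def exclude_nonrepresentative_tags(
    det: pd.DataFrame,
    config: StudyConfig,
    horizon_days: int = 5,
    report: CurationReport | None = None,
) -> tuple[pd.DataFrame, CurationReport]:
    """Exclude tags whose entire history lies in the study's first days.

    A tag detected only within the first ``horizon_days`` local days of the
    study (day indices 0..horizon_days-1 from ``study_start``) is considered
    non-representative of any movement pattern.
    """
    if report is None:
        report = CurationReport(n_input=len(det))
    if det.empty:
        report.n_output = 0
        return det.reset_index(drop=True), report
    day = config.local_day(det["timestamp"])
    day_index = (day - pd.Timestamp(config.study_start)).dt.days
    last = day_index.groupby(det["tag_id"]).max()
    bad = set(last.index[last < horizon_days])
    for tag in sorted(bad):
        report.excluded_tags.append(
            (tag, f"detections only within first {horizon_days} days of study")
        )
    mask = ~det["tag_id"].isin(bad)
    report.n_nonrepresentative_removed += int((~mask).sum())
    out = det[mask].reset_index(drop=True)
    report.n_output = len(out)
    return out, report


def flag_stationary_tags(
    det: pd.DataFrame,
    config: StudyConfig,
    min_span_days: int = 30,
    max_receivers: int = 1,
) -> list[str]:
    """Flag tags stuck at one receiver, suggesting tag loss/expulsion.

    A tag is flagged when it has a run of >= ``min_span_days`` days with no
    gap longer than 1 day during which it is detected at no more than
    ``max_receivers`` distinct receivers (all days of the run together).
    """
    flagged = []
    if det.empty:
        return flagged
    day = config.local_day(det["timestamp"])
    per_day = (
        det.assign(day=day)
        .groupby(["tag_id", "day"])["receiver_id"]
        .agg(lambda s: frozenset(s))
    )
    for tag in per_day.index.get_level_values(0).unique():
        days = per_day.loc[tag]
        dates = list(days.index.sort_values())
        i = 0
        while i < len(dates):
            j = i
            receivers = set(days.loc[dates[i]])
            while (
                j + 1 < len(dates)
                and (dates[j + 1] - dates[j]).days <= 1
                and len(receivers | set(days.loc[dates[j + 1]])) <= max_receivers
            ):
                receivers |= set(days.loc[dates[j + 1]])
                j += 1
            span = (dates[j] - dates[i]).days + 1
            if span >= min_span_days and len(receivers) <= max_receivers:
                flagged.append(str(tag))
                break
            i = j + 1
    return flagged


def curate(
    det: pd.DataFrame,
    config: StudyConfig,
    tagging_days=(),
    collision_window: float = 1.0,
    horizon_days: int = 5,
    stationary_min_span_days: int = 30,
    exclude_stationary: bool = False,
) -> tuple[pd.DataFrame, CurationReport]:
    """Full curation chain in the canonical order, with a report.

    Order matters and is fixed: collisions -> daily singletons -> tagging
    window -> non-representative tags.  Stationary tags are flagged and only
    excluded when ``exclude_stationary`` is set.
    """
    report = CurationReport(n_input=len(det))
    step = remove_collisions(det, window=collision_window)
    report.n_collision_removed = len(det) - len(step)
    prev = step
    step = remove_daily_singletons(prev, config)
    report.n_singleton_removed = len(prev) - len(step)
    prev = step
    step = drop_tagging_window(prev, tagging_days, config)
    report.n_tagging_window_removed = len(prev) - len(step)
    step, report = exclude_nonrepresentative_tags(
        step, config, horizon_days=horizon_days, report=report
    )
    report.stationary_tags = flag_stationary_tags(
        step, config, min_span_days=stationary_min_span_days
    )
    if exclude_stationary and report.stationary_tags:
        mask = ~step["tag_id"].isin(report.stationary_tags)
        for tag in report.stationary_tags:
            report.excluded_tags.append((tag, "stationary at a single receiver"))
        report.n_nonrepresentative_removed += int((~mask).sum())
        step = step[mask].reset_index(drop=True)
    report.n_output = len(step)
    report.validate()
    return step, report
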