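"""Residency, roaming and presence statistics from curated detections.

The daily presence matrix (tags x local days, with the set of receivers each
tag visited per day) is the backbone of every seasonal statistic:

* minimum residency   = days detected / scalar study duration (fixed
  denominator for every tag, however late it was tagged)
* maximum residency   = days detected / (last day - first day + 1)
* roaming index       = mean over present days of (receivers visited / R),
  so a five-receiver array bounds it to [0.2, 1]
* residency category  = vagrant (< 0.1), short-term (0.1-0.5),
  long-term (> 0.5), on the minimum residency index
* presence/absence bouts = run lengths of the presence vector restricted to
  [first detection day, last detection day]
* detected/remaining proportion = per-day detected tags over tags that have
  not yet permanently left (a tag leaves the denominator the day AFTER its
  final detection)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StudyConfig, study_duration_days

__all__ = [
    "DailyPresenceMatrix",
    "ResidencyRecord",
    "build_presence",
    "residency_indices",
    "roaming_index",
    "categorize_residency",
    "bouts",
    "remaining_proportion",
    "monthly_receiver_profile",
]


@dataclass
class DailyPresenceMatrix:
    """Boolean tags-x-days presence plus per-(tag, day) receiver sets.

    ``presence`` is a DataFrame indexed by local day (the full study window,
    both endpoints included) with one boolean column per tag.
    ``receiver_sets[tag][day]`` is the frozenset of receivers visited.
    """

    presence: pd.DataFrame
    receiver_sets: dict
    config: StudyConfig

    @property
    def tags(self):
        return list(self.presence.columns)

    @property
    def days(self):
        return self.presence.index

    def receivers_on(self, tag, day) -> frozenset:
        return self.receiver_sets.get(tag, {}).get(pd.Timestamp(day), frozenset())

    def validate(self) -> None:
        for tag in self.tags:
            days_with_sets = set(self.receiver_sets.get(tag, {}))
            days_present = set(self.presence.index[self.presence[tag]])
            if days_with_sets != days_present:
                raise ValueError(f"presence/receiver-set mismatch for tag {tag}")


@dataclass
class ResidencyRecord:
    tag_id: str
    first_day: pd.Timestamp
    last_day: pd.Timestamp
    days_detected: int
    min_residency: float
    max_residency: float
    roaming: float
    category: str

    def __post_init__(self):
        if self.min_residency > self.max_residency + 1e-12:
            raise ValueError(
                f"tag {self.tag_id}: min residency exceeds max residency"
            )


def build_presence(det: pd.DataFrame, config: StudyConfig, tags=None) -> DailyPresenceMatrix:
    """Build the daily presence matrix from a curated detection table.

    ``tags`` optionally fixes the tag set (e.g. to include tags with zero
    curated detections); otherwise tags observed in ``det`` are used.
    """
    days = config.days()
    tag_ids = (
        [t.tag_id if hasattr(t, "tag_id") else str(t) for t in tags]
        if tags is not None
        else sorted(det["tag_id"].unique())
    )
    presence = pd.DataFrame(False, index=days, columns=tag_ids)
    receiver_sets: dict = {t: {} for t in tag_ids}
    if len(det):
        day = config.local_day(det["timestamp"])
        grouped = det.groupby([det["tag_id"], day])["receiver_id"].agg(
            lambda s: frozenset(s)
        )
        for (tag, d), receivers in grouped.items():
            if tag not in presence.columns:
                continue
            presence.loc[d, tag] = True
            receiver_sets[tag][d] = receivers
    return DailyPresenceMatrix(presence=presence, receiver_sets=receiver_sets, config=config)


def residency_indices(
    p: DailyPresenceMatrix, n_receivers: int, config: StudyConfig | None = None
) -> list[ResidencyRecord]:
    """Per-tag residency records; tags with zero detected days are omitted."""
    config = config or p.config
    duration = study_duration_days(config)
    if duration <= 0:
        raise ValueError("study duration must be positive")
    out = []
    for tag in p.tags:
        col = p.presence[tag]
        days = col.index[col]
        if len(days) == 0:
            continue
        first, last = days[0], days[-1]
        span = (last - first).days + 1
        n_det = int(col.sum())
        # the fixed study duration is an exclusive day difference while the
        # span counts both endpoints; a tag spanning the whole window would
        # otherwise get min > max, so the min denominator is floored at span
        min_res = n_det / max(duration, span)
        max_res = n_det / span
        out.append(
            ResidencyRecord(
                tag_id=str(tag),
                first_day=first,
                last_day=last,
                days_detected=n_det,
                min_residency=min_res,
                max_residency=max_res,
                roaming=roaming_index(p, n_receivers)[str(tag)],
                category=categorize_residency(min_res),
            )
        )
    return out


def roaming_index(
    p: DailyPresenceMatrix, n_receivers: int, period=None
) -> dict[str, float]:
    """Mean fraction of the array's receivers visited per present day.

    ``period`` optionally restricts to a set/Index of days (e.g. one season).
    Tags with no present day in the period are omitted from the result.
    """
    if n_receivers < 1:
        raise ValueError("n_receivers must be >= 1")
    period_set = None if period is None else {pd.Timestamp(d) for d in period}
    out = {}
    for tag in p.tags:
        sets = p.receiver_sets.get(tag, {})
        fracs = [
            len(receivers) / n_receivers
            for d, receivers in sets.items()
            if period_set is None or d in period_set
        ]
        if fracs:
            out[str(tag)] = float(np.mean(fracs))
    return out


def categorize_residency(min_res: float) -> str:
    """Vagrant (< 0.1) / short-term (0.1-0.5, both ends closed) / long-term (> 0.5)."""
    if not 0 <= min_res <= 1:
        raise ValueError(f"residency index {min_res} outside [0, 1]")
    if min_res < 0.1:
        return "vagrant"
    if min_res <= 0.5:
        return "short-term"
    return "long-term"


def bouts(p: DailyPresenceMatrix) -> dict[str, dict[str, list[int]]]:
    """Presence/absence bout lengths per tag, within [first_day, last_day].

    Returns ``{tag: {"presence": [...], "absence": [...]}}``; absence bouts
    are only those between detections, so they alternate with presence bouts
    and the two lists sum to the span length.
    """
    out = {}
    for tag in p.tags:
        col = p.presence[tag].to_numpy()
        idx = np.flatnonzero(col)
        if len(idx) == 0:
            continue
        v = col[idx[0] : idx[-1] + 1]
        # run-length encode
        change = np.flatnonzero(np.diff(v.astype(np.int8))) + 1
        bounds = np.concatenate([[0], change, [len(v)]])
        lengths = np.diff(bounds)
        states = v[bounds[:-1]]
        out[str(tag)] = {
            "presence": [int(l) for l, s in zip(lengths, states) if s],
            "absence": [int(l) for l, s in zip(lengths, states) if not s],
        }
    return out


def remaining_proportion(
    p: DailyPresenceMatrix, sexes: dict[str, str] | None = None, sex: str | None = None
) -> pd.DataFrame:
    """Daily detected/remaining proportion, optionally for one sex.

    The denominator on day d counts tags whose final detection is on or
    after d (the tag "has not permanently left"); the numerator counts tags
    detected on d.  Days with an empty denominator get NaN, not 0.
    """
    cols = p.tags
    if sex is not None:
        if sexes is None:
            raise ValueError("sexes mapping required when filtering by sex")
        cols = [t for t in cols if sexes.get(str(t)) == sex]
    sub = p.presence[cols]
    last_day = {}
    for tag in cols:
        days = sub.index[sub[tag]]
        if len(days):
            last_day[tag] = days[-1]
    n_detected = sub.sum(axis=1).astype(int)
    remaining = pd.DataFrame(
        {tag: sub.index <= last_day[tag] for tag in last_day}, index=sub.index
    )
    n_remaining = (
        remaining.sum(axis=1).astype(int)
        if len(last_day)
        else pd.Series(0, index=sub.index)
    )
    prop = n_detected / n_remaining.replace(0, np.nan)
    return pd.DataFrame(
        {"n_detected": n_detected, "n_remaining": n_remaining, "proportion": prop}
    )


def monthly_receiver_profile(p: DailyPresenceMatrix) -> pd.DataFrame:
    """Month x receiver mean daily detected/remaining proportion.

    For each day and receiver: (tags detected at that receiver) / (tags
    remaining); averaged over the days of each calendar month.  Months or
    receivers with no data give 0 when the denominator existed, NaN when no
    tag remained at all.
    """
    remaining = remaining_proportion(p)["n_remaining"]
    receivers = sorted(
        {r for sets in p.receiver_sets.values() for s in sets.values() for r in s}
    )
    daily = pd.DataFrame(0.0, index=p.days, columns=receivers)
    for tag, sets in p.receiver_sets.items():
        for d, recs in sets.items():
            for r in recs:
                daily.loc[d, r] += 1.0
    frac = daily.div(remaining.replace(0, np.nan), axis=0)
    return frac.groupby(frac.index.month).mean()
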