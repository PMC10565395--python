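"""Assemble the three model tables from presence, detections and covariates.

* seasonal detection: one row per (tag, day) from the study start through the
  tag's last detection day; response 1/0 detected that day.
* seasonal roaming: one row per (tag, present day); response = (receivers
  visited, total receivers) binomial counts, plus prop_f / prop_m — the
  detected/remaining proportion of each sex that day.
* intra-day detection: one row per (tag, local hour) on the tag's present
  days; response 1/0 detected in that hour, tide covariates joined by hour.

Covariates with missing values are left as NaN; the model drops incomplete
rows listwise and reports the count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import StudyConfig
from .gam import ModelSpec, Smooth
from .residency import DailyPresenceMatrix, remaining_proportion

__all__ = [
    "build_seasonal_table",
    "build_roaming_table",
    "build_intraday_table",
    "seasonal_candidates",
    "roaming_candidates",
    "intraday_candidates",
]


def _tag_attrs(tags) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tag_id": [t.tag_id for t in tags],
            "sex": [t.sex for t in tags],
            "total_length": [t.total_length for t in tags],
        }
    ).set_index("tag_id")


def build_seasonal_table(
    p: DailyPresenceMatrix,
    tags,
    sst: pd.Series | None = None,
    tide_amplitude: pd.Series | None = None,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Per-tag daily 0/1 detection rows through each tag's last detection."""
    config = config or p.config
    attrs = _tag_attrs(tags)
    rows = []
    for tag in p.tags:
        col = p.presence[tag]
        detected_days = col.index[col]
        if len(detected_days) == 0:
            continue
        days = p.presence.index[p.presence.index <= detected_days[-1]]
        df = pd.DataFrame(
            {
                "tag_id": str(tag),
                "day": days,
                "detected": col.loc[days].astype(int).to_numpy(),
            }
        )
        rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["tag_id", "day", "detected", "sex", "total_length", "month",
                     "sst", "tide_amplitude", "season"]
        )
    out = pd.concat(rows, ignore_index=True)
    out = out.join(attrs, on="tag_id")
    out["month"] = out["day"].dt.month
    out["season"] = out["month"].map(config.season_of_month)
    out["sst"] = out["day"].map(sst) if sst is not None else np.nan
    out["tide_amplitude"] = (
        out["day"].map(tide_amplitude) if tide_amplitude is not None else np.nan
    )
    return out


def build_roaming_table(
    p: DailyPresenceMatrix,
    tags,
    n_receivers: int,
    sst: pd.Series | None = None,
    tide_amplitude: pd.Series | None = None,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Binomial (visited, total) rows for each present day, with prop_f/prop_m."""
    config = config or p.config
    attrs = _tag_attrs(tags)
    sexes = {t.tag_id: t.sex for t in tags}
    prop_f = remaining_proportion(p, sexes=sexes, sex="female")["proportion"]
    prop_m = remaining_proportion(p, sexes=sexes, sex="male")["proportion"]
    rows = []
    for tag in p.tags:
        for day, receivers in sorted(p.receiver_sets.get(tag, {}).items()):
            rows.append((str(tag), day, len(receivers)))
    if not rows:
        return pd.DataFrame(
            columns=["tag_id", "day", "visited", "n_receivers", "sex", "total_length",
                     "month", "season", "prop_f", "prop_m", "sst", "tide_amplitude"]
        )
    out = pd.DataFrame(rows, columns=["tag_id", "day", "visited"])
    out["n_receivers"] = n_receivers
    out = out.join(attrs, on="tag_id")
    out["month"] = out["day"].dt.month
    out["season"] = out["month"].map(config.season_of_month)
    out["prop_f"] = out["day"].map(prop_f)
    out["prop_m"] = out["day"].map(prop_m)
    out["sst"] = out["day"].map(sst) if sst is not None else np.nan
    out["tide_amplitude"] = (
        out["day"].map(tide_amplitude) if tide_amplitude is not None else np.nan
    )
    return out


def build_intraday_table(
    det: pd.DataFrame,
    p: DailyPresenceMatrix,
    tags,
    tide: pd.DataFrame | None = None,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """Hourly 0/1 detection rows on present days, tide covariates per hour.

    The tide table (from :func:`tidegate.tides.build_tide_series`) is indexed
    by local hourly instants; each (day, hour) row joins the matching hour.
    """
    config = config or p.config
    attrs = _tag_attrs(tags)
    day = config.local_day(det["timestamp"])
    hour = config.local_hour(det["timestamp"])
    detected = set(
        zip(det["tag_id"].astype(str), day, hour)
    )
    rows = []
    for tag in p.tags:
        col = p.presence[tag]
        for d in col.index[col]:
            for h in range(24):
                rows.append(
                    (str(tag), d, h, int((str(tag), d, h) in detected))
                )
    if not rows:
        return pd.DataFrame(
            columns=["tag_id", "day", "hour", "detected", "sex", "total_length",
                     "season", "tide_height", "tide_height_class", "tide_direction",
                     "tide_strength"]
        )
    out = pd.DataFrame(rows, columns=["tag_id", "day", "hour", "detected"])
    out = out.join(attrs, on="tag_id")
    out["season"] = out["day"].dt.month.map(config.season_of_month)
    if tide is not None:
        instant = out["day"] + pd.to_timedelta(out["hour"], unit="h")
        out["tide_height"] = instant.map(tide["height"])
        out["tide_height_class"] = instant.map(tide["height_class"])
        out["tide_direction"] = instant.map(tide["direction"])
        out["tide_strength"] = instant.map(tide["strength"])
    else:
        for c in ("tide_height", "tide_height_class", "tide_direction", "tide_strength"):
            out[c] = np.nan
    return out


# ---------------------------------------------------------------------------
# candidate sets mirroring the published nesting pattern:
# a global model, drop-one-term variants, and random-effect variants
# (tag-by-sex, tag, none).


def seasonal_candidates(month_df: int = 6, cont_df: int = 6) -> list[ModelSpec]:
    month = Smooth("month", basis="cc", df=month_df, bounds=(0.5, 12.5))
    month_by = Smooth("month", basis="cc", df=month_df, bounds=(0.5, 12.5), by="sex")
    tl = Smooth("total_length", basis="ps", df=cont_df)
    sst = Smooth("sst", basis="ps", df=cont_df)
    ta = Smooth("tide_amplitude", basis="ps", df=cont_df)
    full = (tl, month, month_by, sst, ta)
    return [
        ModelSpec("global+tag:sex", "detected", full, ("sex",), random="tag:sex"),
        ModelSpec("global+tag", "detected", full, ("sex",), random="tag"),
        ModelSpec(
            "drop_TL+tag", "detected", (month, month_by, sst, ta), ("sex",), random="tag"
        ),
        ModelSpec(
            "drop_month_sex+tag", "detected", (tl, month, sst, ta), ("sex",), random="tag"
        ),
        ModelSpec("global+none", "detected", full, ("sex",), random=None),
    ]


def roaming_candidates(cont_df: int = 6) -> list[ModelSpec]:
    tl = Smooth("total_length", basis="ps", df=cont_df)
    pf = Smooth("prop_f", basis="ps", df=cont_df)
    pf_by = Smooth("prop_f", basis="ps", df=cont_df, by="sex")
    pm = Smooth("prop_m", basis="ps", df=cont_df)
    pm_by = Smooth("prop_m", basis="ps", df=cont_df, by="sex")
    sst = Smooth("sst", basis="ps", df=cont_df)
    ta = Smooth("tide_amplitude", basis="ps", df=cont_df)
    full = (tl, pf, pf_by, pm, pm_by, sst, ta)
    kw = dict(trials="n_receivers")
    return [
        ModelSpec("global+tag", "visited", full, ("sex", "season"), random="tag", **kw),
        ModelSpec(
            "reduced+tag", "visited", (pf, pf_by, pm, pm_by, sst), ("sex",),
            random="tag", **kw,
        ),
        ModelSpec(
            "global+tag:sex", "visited", full, ("sex", "season"), random="tag:sex", **kw
        ),
        ModelSpec("global+none", "visited", full, ("sex", "season"), random=None, **kw),
        ModelSpec(
            "drop_sex_props+tag", "visited", (tl, pf, pm, sst, ta), ("sex", "season"),
            random="tag", **kw,
        ),
    ]


def intraday_candidates(hour_df: int = 6, cont_df: int = 6) -> list[ModelSpec]:
    hour = Smooth("hour", basis="cc", df=hour_df, bounds=(-0.5, 23.5))
    hour_by = Smooth("hour", basis="cc", df=hour_df, bounds=(-0.5, 23.5), by="sex")
    tl = Smooth("total_length", basis="ps", df=cont_df)
    cats = (
        "sex",
        "tide_height_class",
        "tide_height_class:sex",
        "tide_direction",
        "tide_direction:sex",
    )
    return [
        ModelSpec("global+tag", "detected", (hour, hour_by), cats, random="tag"),
        ModelSpec("global_TL+tag", "detected", (tl, hour, hour_by), cats, random="tag"),
        ModelSpec(
            "global_TL+tag:sex", "detected", (tl, hour, hour_by), cats, random="tag:sex"
        ),
        ModelSpec("global_TL+none", "detected", (tl, hour, hour_by), cats, random=None),
        ModelSpec(
            "no_sex_interactions+none", "detected", (tl, hour),
            ("sex", "tide_height_class", "tide_direction", "tide_strength", "season"),
            random=None,
        ),
    ]
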