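"""Readers and writers for the standard telemetry input files.

All inputs are plain delimited text (comma or tab), in the style of
receiver-export files:

* detections: ``timestamp, tag_id, receiver_id``
* receivers:  ``receiver_id, x, y, deploy_date, recover_date, status``
* tags:       ``tag_id, sex, total_length, tagging_date`` (+ optional
  ``emission_min, emission_max``)
* tide extremes: ``time, height, kind`` with kind in {high, low}
* sst:        ``date, sst_c``
* water polygon: GeoJSON (or WKT) in planar metric coordinates

A ``column_map`` argument adapts vendor exports whose headers differ.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import shapely
import shapely.geometry

from .config import StudyConfig, study_duration_days

__all__ = [
    "Receiver",
    "TagDeployment",
    "TideExtreme",
    "read_detections",
    "write_detections",
    "read_receivers",
    "read_tags",
    "read_tide_extremes",
    "read_sst",
    "read_water_polygon",
    "study_duration_days",
]

log = logging.getLogger(__name__)

DETECTION_COLUMNS = ["timestamp", "tag_id", "receiver_id"]


@dataclass(frozen=True)
class Receiver:
    receiver_id: str
    x: float
    y: float
    deploy_date: dt.date
    recover_date: dt.date
    status: str = "active"  # active | lost

    def __post_init__(self):
        if self.recover_date <= self.deploy_date:
            raise ValueError(
                f"receiver {self.receiver_id}: deploy_date must precede recover_date"
            )
        if self.status not in ("active", "lost"):
            raise ValueError(f"receiver {self.receiver_id}: bad status {self.status!r}")

    @property
    def position(self):
        return (self.x, self.y)


@dataclass(frozen=True)
class TagDeployment:
    tag_id: str
    sex: str  # female | male
    total_length: float  # cm
    tagging_date: dt.date
    emission_min: float = 60.0  # s
    emission_max: float = 180.0  # s

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"tag {self.tag_id}: sex must be female/male")
        if not (100.0 < self.total_length < 300.0):
            raise ValueError(
                f"tag {self.tag_id}: total_length {self.total_length} cm outside (100, 300)"
            )
        if not self.emission_min < self.emission_max:
            raise ValueError(f"tag {self.tag_id}: emission interval min must be < max")


@dataclass(frozen=True)
class TideExtreme:
    time: dt.datetime
    height: float  # m
    kind: str  # high | low

    def __post_init__(self):
        if self.kind not in ("high", "low"):
            raise ValueError(f"tide extreme kind must be high/low, got {self.kind!r}")


def _read_table(path, column_map=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if column_map:
        df = df.rename(columns={v.lower(): k for k, v in column_map.items()})
    return df


def read_detections(
    path,
    config: StudyConfig,
    receivers=None,
    tags=None,
    on_unknown: str = "drop",
    column_map: dict | None = None,
) -> pd.DataFrame:
    """Read a raw detections file into a time-sorted detection table.

    Rows whose local day falls outside ``[study_start, study_end]`` are
    dropped (count logged).  Unknown receiver/tag ids are dropped or raise,
    depending on ``on_unknown`` ('drop' | 'error'); the check only applies
    when ``receivers`` / ``tags`` are given.

    Returns a DataFrame with columns ``timestamp`` (datetime64),
    ``tag_id``, ``receiver_id`` (str), sorted by timestamp.
    """
    if on_unknown not in ("drop", "error"):
        raise ValueError("on_unknown must be 'drop' or 'error'")
    df = _read_table(path, column_map)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing detection columns {missing}")
    df = df[DETECTION_COLUMNS].copy()
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        bad = df.index[ts.isna()][0]
        raise ValueError(
            f"{path}: unparseable timestamp {df.loc[bad, 'timestamp']!r} at row {bad}"
        )
    df["timestamp"] = ts
    df["tag_id"] = df["tag_id"].astype(str)
    df["receiver_id"] = df["receiver_id"].astype(str)

    day = config.local_day(df["timestamp"])
    in_window = (day >= pd.Timestamp(config.study_start)) & (
        day <= pd.Timestamp(config.study_end)
    )
    n_out = int((~in_window).sum())
    if n_out:
        log.info("read_detections: dropped %d rows outside the study window", n_out)
    df = df[in_window]

    for col, known in (("receiver_id", receivers), ("tag_id", tags)):
        if known is None:
            continue
        ids = {k.receiver_id if col == "receiver_id" else k.tag_id for k in known}
        unknown = ~df[col].isin(ids)
        if unknown.any():
            offending = sorted(df.loc[unknown, col].unique())
            if on_unknown == "error":
                raise ValueError(f"{path}: unknown {col} values {offending}")
            log.info(
                "read_detections: dropped %d rows with unknown %s %s",
                int(unknown.sum()), col, offending,
            )
            df = df[~unknown]

    return df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def write_detections(det: pd.DataFrame, path) -> None:
    """Write a detection table; ``read_detections`` round-trips it exactly."""
    out = det[DETECTION_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out.to_csv(path, index=False)


def read_receivers(path, water=None, column_map=None) -> list[Receiver]:
    df = _read_table(path, column_map)
    recs = [
        Receiver(
            receiver_id=str(r.receiver_id),
            x=float(r.x),
            y=float(r.y),
            deploy_date=pd.Timestamp(r.deploy_date).date(),
            recover_date=pd.Timestamp(r.recover_date).date(),
            status=str(getattr(r, "status", "active")),
        )
        for r in df.itertuples(index=False)
    ]
    if water is not None:
        for rec in recs:
            if not water.buffer(1e-6).covers(shapely.geometry.Point(rec.x, rec.y)):
                raise ValueError(
                    f"receiver {rec.receiver_id} at {rec.position} lies outside the water polygon"
                )
    return recs


def read_tags(path, column_map=None) -> list[TagDeployment]:
    df = _read_table(path, column_map)
    out = []
    for r in df.itertuples(index=False):
        kwargs = dict(
            tag_id=str(r.tag_id),
            sex=str(r.sex),
            total_length=float(r.total_length),
            tagging_date=pd.Timestamp(r.tagging_date).date(),
        )
        if hasattr(r, "emission_min"):
            kwargs["emission_min"] = float(r.emission_min)
        if hasattr(r, "emission_max"):
            kwargs["emission_max"] = float(r.emission_max)
        out.append(TagDeployment(**kwargs))
    return out


def read_tide_extremes(path, column_map=None) -> list[TideExtreme]:
    """Read alternating high/low tide extremes; non-alternation is an error."""
    df = _read_table(path, column_map)
    if df.empty:
        raise ValueError(f"{path}: empty tide extremes file")
    df["time"] = pd.to_datetime(df["time"], format="ISO8601")
    df = df.sort_values("time")
    extremes = [
        TideExtreme(time=r.time.to_pydatetime(), height=float(r.height), kind=str(r.kind))
        for r in df.itertuples(index=False)
    ]
    validate_alternation(extremes)
    return extremes


def validate_alternation(extremes) -> None:
    for a, b in zip(extremes, extremes[1:]):
        if a.kind == b.kind:
            raise ValueError(
                f"tide extremes do not alternate: {a.kind} at {a.time} "
                f"followed by {b.kind} at {b.time}"
            )


def read_sst(path, column_map=None) -> pd.Series:
    """Daily sea-surface temperature series indexed by date."""
    df = _read_table(path, column_map)
    if df.empty:
        raise ValueError(f"{path}: empty SST file")
    idx = pd.to_datetime(df["date"]).dt.normalize()
    return pd.Series(df["sst_c"].astype(float).values, index=idx, name="sst_c")


def read_water_polygon(path):
    """Read the inlet water polygon from GeoJSON (``.geojson``/``.json``) or WKT.

    Coordinates are planar metres.  Self-intersecting polygons are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".geojson", ".json"):
        obj = json.loads(text)
        if obj.get("type") == "FeatureCollection":
            obj = obj["features"][0]["geometry"]
        elif obj.get("type") == "Feature":
            obj = obj["geometry"]
        poly = shapely.geometry.shape(obj)
    else:
        poly = shapely.from_wkt(text.strip())
    if poly.is_empty:
        raise ValueError(f"{path}: empty polygon")
    if not poly.is_valid:
        raise ValueError(f"{path}: invalid (e.g. self-intersecting) polygon")
    return poly
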