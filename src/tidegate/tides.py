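"""Hourly tide series and categorical tide covariates.

Astronomic predictions usually come as tables of high/low extremes for the
nearest main port.  Between consecutive extremes the height is approximated
by the standard cosine (sinusoidal) interpolant

    h(t) = h1 + (h2 - h1) * (1 - cos(pi * (t - t1) / (t2 - t1))) / 2

sampled on the hour.  From the hourly series the covariates used by the
intra-day detection model are derived:

* height class: low / intermediate / high at the empirical 0.25 and 0.75
  quantiles of the full hourly series (linear-interpolation "type 7"
  estimator, the numpy default — class boundaries depend on the estimator,
  so it is fixed and documented);
* direction: inflow while rising, outflow while falling; an exact slack
  hour inherits the previous hour's label;
* strength: "weak" near slack (|height - height at the nearest extreme|
  below a threshold, default 0.5 m), "strong" otherwise.

An optional affine-plus-lag calibration against in-situ logger data is
provided (offset + scale * predicted(t - lag), lag on a 5-min grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TideExtreme, validate_alternation

__all__ = [
    "TideCalibration",
    "interpolate_hourly",
    "daily_amplitude",
    "classify_height",
    "classify_direction",
    "classify_strength",
    "build_tide_series",
    "calibrate",
    "apply_calibration",
]

MAX_EXTREME_GAP_HOURS = 15.0


@dataclass(frozen=True)
class TideCalibration:
    offset: float  # m
    scale: float
    lag_minutes: float
    rmse: float  # m

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("calibration scale must be positive")


def interpolate_hourly(extremes: list[TideExtreme]) -> pd.Series:
    """Cosine-interpolated heights sampled on the hour between the extremes."""
    if len(extremes) < 2:
        raise ValueError("need at least two tide extremes")
    extremes = sorted(extremes, key=lambda e: e.time)
    validate_alternation(extremes)
    times = pd.to_datetime([e.time for e in extremes])
    heights = np.array([e.height for e in extremes], dtype=float)
    gaps = np.diff(times.view(np.int64)) / 3.6e12
    if (gaps > MAX_EXTREME_GAP_HOURS).any():
        i = int(np.argmax(gaps > MAX_EXTREME_GAP_HOURS))
        raise ValueError(
            f"gap of {gaps[i]:.1f} h between extremes at {times[i]} and {times[i + 1]} "
            f"exceeds {MAX_EXTREME_GAP_HOURS} h"
        )
    start = times[0].ceil("h")
    end = times[-1].floor("h")
    hours = pd.date_range(start, end, freq="h")
    t = hours.view(np.int64).astype(float)
    knots = times.view(np.int64).astype(float)
    seg = np.clip(np.searchsorted(knots, t, side="right") - 1, 0, len(knots) - 2)
    t1, t2 = knots[seg], knots[seg + 1]
    h1, h2 = heights[seg], heights[seg + 1]
    frac = (t - t1) / (t2 - t1)
    h = h1 + (h2 - h1) * (1 - np.cos(np.pi * frac)) / 2
    # an on-the-hour sample exactly at an extreme gets that extreme's height
    exact = np.isin(t, knots)
    if exact.any():
        h[exact] = heights[np.searchsorted(knots, t[exact])]
    return pd.Series(h, index=hours, name="height")


def daily_amplitude(extremes: list[TideExtreme], utc_offset_hours: float = 0.0) -> pd.Series:
    """Per-local-day tide amplitude: max high minus min low among that day's extremes.

    Days lacking either a high or a low extreme give NaN.
    """
    if not extremes:
        raise ValueError("no tide extremes")
    rows = pd.DataFrame(
        {
            "day": [
                (pd.Timestamp(e.time) + pd.Timedelta(hours=utc_offset_hours)).normalize()
                for e in extremes
            ],
            "height": [e.height for e in extremes],
            "kind": [e.kind for e in extremes],
        }
    )
    highs = rows[rows["kind"] == "high"].groupby("day")["height"].max()
    lows = rows[rows["kind"] == "low"].groupby("day")["height"].min()
    days = pd.date_range(rows["day"].min(), rows["day"].max(), freq="D")
    amp = highs.reindex(days) - lows.reindex(days)
    amp.name = "tide_amplitude"
    return amp


def classify_height(series: pd.Series) -> pd.Series:
    """Low / intermediate / high by the 0.25 and 0.75 quantiles of the series."""
    q25, q75 = np.quantile(series.to_numpy(), [0.25, 0.75])  # linear, "type 7"
    if q25 >= q75:  # degenerate (e.g. constant) series
        return pd.Series("intermediate", index=series.index, name="height_class")
    labels = np.where(
        series.to_numpy() <= q25,
        "low",
        np.where(series.to_numpy() >= q75, "high", "intermediate"),
    )
    return pd.Series(labels, index=series.index, name="height_class")


def classify_direction(series: pd.Series) -> pd.Series:
    """Inflow while the tide rises, outflow while it falls; slack ties inherit."""
    diff = series.diff().to_numpy()
    labels = np.empty(len(series), dtype=object)
    prev = None
    for i in range(len(series)):
        d = diff[i]
        if i == 0 or np.isnan(d) or d == 0:
            labels[i] = prev
        else:
            labels[i] = "inflow" if d > 0 else "outflow"
            prev = labels[i]
    # leading undefined hours take the first defined label
    prev = next((l for l in labels if l is not None), "inflow")
    vals = []
    for l in labels:
        if l is None:
            vals.append(prev)
        else:
            prev = l
            vals.append(l)
    return pd.Series(vals, index=series.index, name="direction")


def classify_strength(
    series: pd.Series, extremes: list[TideExtreme], threshold: float = 0.5
) -> pd.Series:
    """Weak near slack (|h - height at nearest extreme| < threshold), else strong."""
    ext_t = pd.to_datetime([e.time for e in sorted(extremes, key=lambda e: e.time)])
    ext_h = np.array(
        [e.height for e in sorted(extremes, key=lambda e: e.time)], dtype=float
    )
    t = series.index.view(np.int64).astype(float)
    kt = ext_t.view(np.int64).astype(float)
    pos = np.searchsorted(kt, t)
    left = np.clip(pos - 1, 0, len(kt) - 1)
    right = np.clip(pos, 0, len(kt) - 1)
    nearest = np.where(np.abs(t - kt[left]) <= np.abs(kt[right] - t), left, right)
    weak = np.abs(series.to_numpy() - ext_h[nearest]) < threshold
    return pd.Series(
        np.where(weak, "weak", "strong"), index=series.index, name="strength"
    )


def build_tide_series(
    extremes: list[TideExtreme],
    slack_threshold: float = 0.5,
    calibration: TideCalibration | None = None,
) -> pd.DataFrame:
    """Hourly tide table: height plus height_class, direction and strength."""
    h = interpolate_hourly(extremes)
    if calibration is not None:
        h = apply_calibration(h, calibration)
    return pd.DataFrame(
        {
            "height": h,
            "height_class": classify_height(h),
            "direction": classify_direction(h),
            "strength": classify_strength(h, extremes, threshold=slack_threshold),
        }
    )


def calibrate(
    predicted: pd.Series,
    logger: pd.Series,
    max_lag_minutes: float = 120.0,
    lag_step_minutes: float = 5.0,
) -> TideCalibration:
    """Fit logger ~ offset + scale * predicted(t - lag) by least squares.

    The lag is grid-searched over +/- ``max_lag_minutes`` in steps of
    ``lag_step_minutes``; offset and scale by ordinary least squares at each
    lag; the (lag, offset, scale) triple with smallest RMSE wins.
    """
    lags = np.arange(-max_lag_minutes, max_lag_minutes + lag_step_minutes / 2,
                     lag_step_minutes)
    pt = predicted.index.view(np.int64).astype(float) / 1e9
    pv = predicted.to_numpy().astype(float)
    lt = logger.index.view(np.int64).astype(float) / 1e9
    lv = logger.to_numpy().astype(float)
    best = None
    for lag in lags:
        x = np.interp(lt - lag * 60.0, pt, pv)
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, lv, rcond=None)
        resid = lv - A @ coef
        rmse = float(np.sqrt(np.mean(resid**2)))
        if best is None or rmse < best[0] - 1e-12:
            best = (rmse, float(coef[0]), float(coef[1]), float(lag))
    rmse, offset, scale, lag = best
    return TideCalibration(offset=offset, scale=scale, lag_minutes=lag, rmse=rmse)


def apply_calibration(series: pd.Series, cal: TideCalibration) -> pd.Series:
    """Transform a predicted series onto the logger scale."""
    t = series.index.view(np.int64).astype(float) / 1e9
    shifted = np.interp(t - cal.lag_minutes * 60.0, t, series.to_numpy().astype(float))
    return pd.Series(
        cal.offset + cal.scale * shifted, index=series.index, name=series.name
    )
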