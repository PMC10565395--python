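"""Synthetic tidal-inlet telemetry generator.

Emulates the statistical structure the pipeline assumes: a gate array of
five receivers ~2 km apart along a narrow ~15 km inlet, 18 tagged sharks
(11 females, 7 males) with 60-180 s random emission intervals, seasonal
presence peaking in December, sex-specific permanent departures (males
leave abruptly late in the high season, females taper off), within-inlet
movement as an Ornstein-Uhlenbeck process along the inlet axis whose mean
drifts with tide height for males, semidiurnal (M2, 12.42 h) tides with a
spring-neap envelope, logistic distance-dependent detection with effective
range of a few hundred metres, and a seasonal SST curve (min 8 degC in
August, max 18 degC in February).

Every latent parameter and per-tag departure day is recorded in a truth
dictionary (written as ``truth.json``), the single source for
parameter-recovery assertions.  With a fixed seed the outputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.geometry

from .config import StudyConfig
from .io import Receiver, TagDeployment, TideExtreme

__all__ = ["SimScenario", "SimResult", "simulate", "write_outputs", "sst_curve"]

M2_PERIOD_H = 12.42  # principal lunar semidiurnal constituent
SPRING_NEAP_DAYS = 14.77

DEFAULT_Q_MONTH = {
    1: 0.80, 2: 0.60, 3: 0.30, 4: 0.18, 5: 0.12, 6: 0.10,
    7: 0.10, 8: 0.12, 9: 0.30, 10: 0.60, 11: 0.85, 12: 0.90,
}
# males: the same peak but a sharper seasonal contrast (their use of the
# inlet is concentrated in the high season, ending in abrupt departures)
DEFAULT_Q_MONTH_MALE = {m: round(q**2, 4) for m, q in DEFAULT_Q_MONTH.items()}


@dataclass
class SimScenario:
    """Latent structure of one simulated study.  Defaults emulate the field setup."""

    study_start: dt.date = dt.date(2019, 11, 1)
    study_end: dt.date = dt.date(2021, 3, 12)
    # geometry (planar metres; x = along-inlet axis, y = across)
    inlet_length: float = 15000.0
    inlet_width: float = 400.0
    receiver_start: float = 6500.0  # upper-half gate array
    receiver_spacing: float = 2000.0
    n_receivers: int = 5
    # animals
    n_females: int = 11
    n_males: int = 7
    # seasonal occupancy probability by calendar month (shared shape)
    q_month: dict = field(default_factory=lambda: dict(DEFAULT_Q_MONTH))
    q_month_male: dict | None = field(
        default_factory=lambda: dict(DEFAULT_Q_MONTH_MALE)
    )  # None -> same curve as females
    # permanent departure hazards (per day)
    male_departure_hazard: float = 0.12  # active only in departure months
    male_departure_months: tuple = (2, 3)  # late high season: abrupt exits
    female_departure_hazard: float = 0.008  # year-round taper after first season
    # movement (OU along the axis)
    ou_relaxation_s: float = 28800.0  # 8 h mean-reversion time
    ou_equilibrium_sd: float = 2000.0  # m
    female_mean_position: float = 10500.0
    male_mean_position: float = 6000.0
    male_tide_drift: float = 1500.0  # m of mean shift per m of tide-height deviation
    # tides
    tide_mean: float = 2.25
    tide_high_amp: float = 1.65  # high ~ mean + amp, low ~ mean - amp
    spring_neap_frac: float = 0.35
    # detection
    detection_d50: float = 250.0  # m, logistic midpoint
    detection_shape: float = 50.0  # m
    tide_detection_coef: float = 0.04  # relative d50 change per m tide deviation
    perfect_detection: bool = False
    # transmitter
    emission_min: float = 60.0
    emission_max: float = 180.0
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for q in self.q_month.values():
            if not 0 <= q <= 1:
                raise ValueError("q(month) must be in [0, 1]")
        if self.emission_min >= self.emission_max:
            raise ValueError("emission interval min must be < max")

    def config(self) -> StudyConfig:
        # simulated timestamps are already local clock time
        return StudyConfig(
            study_start=self.study_start,
            study_end=self.study_end,
            timestamps_are_utc=False,
        )

    def receiver_positions(self) -> np.ndarray:
        x = self.receiver_start + self.receiver_spacing * np.arange(self.n_receivers)
        if (x > self.inlet_length).any():
            raise ValueError("receivers extend beyond the inlet")
        y = np.full(self.n_receivers, self.inlet_width / 2.0)
        return np.column_stack([x, y])

    def water_polygon(self):
        return shapely.geometry.box(0.0, 0.0, self.inlet_length, self.inlet_width)


@dataclass
class SimResult:
    detections: pd.DataFrame
    receivers: list
    tags: list
    tide_extremes: list
    sst: pd.Series
    water: object
    truth: dict
    config: StudyConfig


def sst_curve(days: pd.DatetimeIndex) -> pd.Series:
    """Seasonal SST (degC): max 18 mid-February, min 8 mid-August."""
    doy = days.dayofyear.to_numpy(dtype=float)
    return pd.Series(
        13.0 + 5.0 * np.cos(2 * np.pi * (doy - 46.0) / 365.25), index=days, name="sst_c"
    )


def _tide_extremes(scn: SimScenario, rng) -> list[TideExtreme]:
    t0 = pd.Timestamp(scn.study_start) - pd.Timedelta(days=2)
    t1 = pd.Timestamp(scn.study_end) + pd.Timedelta(days=2)
    n = int((t1 - t0).total_seconds() / 3600.0 / (M2_PERIOD_H / 2.0)) + 2
    times = t0 + pd.to_timedelta(
        np.round(np.arange(n) * M2_PERIOD_H / 2.0 * 3600.0), unit="s"
    )
    phase_sn = (
        (times - t0).total_seconds() / 86400.0 / SPRING_NEAP_DAYS * 2 * np.pi
    )
    envelope = 1.0 + scn.spring_neap_frac * np.sin(phase_sn)
    kinds = np.where(np.arange(n) % 2 == 0, "high", "low")
    heights = np.where(
        kinds == "high",
        scn.tide_mean + scn.tide_high_amp * envelope,
        scn.tide_mean - scn.tide_high_amp * envelope,
    )
    return [
        TideExtreme(time=t.to_pydatetime(), height=float(h), kind=str(k))
        for t, h, k in zip(times, heights, kinds)
    ]


def _hourly_tide(extremes) -> tuple[np.ndarray, np.ndarray]:
    from .tides import interpolate_hourly

    h = interpolate_hourly(extremes)
    t = h.index.view(np.int64).astype(float) / 1e9
    return t, h.to_numpy()


def simulate(scenario: SimScenario) -> SimResult:
    """Run the generator; all randomness comes from ``scenario.seed``."""
    scn = scenario
    rng = np.random.default_rng(scn.seed)
    config = scn.config()
    days = config.days()
    n_days = len(days)
    rec_xy = scn.receiver_positions()
    receivers = [
        Receiver(
            receiver_id=f"R{i + 1}",
            x=float(x),
            y=float(y),
            deploy_date=scn.study_start - dt.timedelta(days=3),
            recover_date=scn.study_end + dt.timedelta(days=1),
        )
        for i, (x, y) in enumerate(rec_xy)
    ]
    tagging_days = [scn.study_start - dt.timedelta(days=k) for k in (3, 2, 1)]
    tags = []
    for i in range(scn.n_females):
        tags.append(
            TagDeployment(
                tag_id=f"F{i + 1:02d}",
                sex="female",
                total_length=float(np.round(rng.uniform(190, 245), 1)),
                tagging_date=tagging_days[i % 3],
                emission_min=scn.emission_min,
                emission_max=scn.emission_max,
            )
        )
    for i in range(scn.n_males):
        tags.append(
            TagDeployment(
                tag_id=f"M{i + 1:02d}",
                sex="male",
                total_length=float(np.round(rng.uniform(183, 230), 1)),
                tagging_date=tagging_days[i % 3],
                emission_min=scn.emission_min,
                emission_max=scn.emission_max,
            )
        )

    extremes = _tide_extremes(scn, rng)
    tide_t, tide_h = _hourly_tide(extremes)
    tide_mean_obs = float(tide_h.mean())
    sst = sst_curve(days)

    q_f = scn.q_month
    q_m = scn.q_month_male or scn.q_month
    theta = 1.0 / scn.ou_relaxation_s
    sigma2 = 2.0 * theta * scn.ou_equilibrium_sd**2

    all_ts, all_tag, all_rec = [], [], []
    departure_day: dict[str, str | None] = {}

    for tag in tags:
        male = tag.sex == "male"
        q_by_month = q_m if male else q_f
        hazard = scn.male_departure_hazard if male else scn.female_departure_hazard
        months_active = scn.male_departure_months if male else tuple(range(1, 13))
        departed = None
        dev = rng.normal(0.0, scn.ou_equilibrium_sd)  # OU deviation from mean
        last_t = None
        for di in range(n_days):
            day = days[di]
            if departed is None and di > 30:
                if day.month in months_active and rng.uniform() < hazard:
                    departed = day
            if departed is not None:
                break
            if rng.uniform() >= q_by_month[day.month]:
                continue
            # transmission times within the day
            day_start = day.value / 1e9
            gaps = rng.uniform(scn.emission_min, scn.emission_max, size=800)
            t = day_start + np.cumsum(gaps)
            t = t[t < day_start + 86400.0]
            if len(t) == 0:
                continue
            # OU deviation, exact discretisation (vectorised via scaled cumsum)
            if last_t is not None:
                dev *= np.exp(-theta * (t[0] - last_t))
                dev += rng.normal(
                    0.0,
                    np.sqrt(
                        sigma2 / (2 * theta) * (1 - np.exp(-2 * theta * (t[0] - last_t)))
                    ),
                )
            A = np.exp(-theta * (t - t[0]))
            dt_steps = np.diff(t, prepend=t[0])
            step_sd = np.sqrt(sigma2 / (2 * theta) * (1 - np.exp(-2 * theta * dt_steps)))
            eta = rng.normal(0.0, 1.0, size=len(t)) * step_sd
            eta[0] = 0.0
            devs = A * (dev + np.cumsum(eta / A))
            dev = float(devs[-1])
            last_t = float(t[-1])
            # quasi-static mean: tide-dependent for males
            height = np.interp(t, tide_t, tide_h)
            mean = (
                scn.male_mean_position + scn.male_tide_drift * (height - tide_mean_obs)
                if male
                else scn.female_mean_position
            )
            x = np.clip(mean + devs, 0.0, scn.inlet_length)
            # detection per receiver
            if scn.perfect_detection:
                nearest = np.argmin(np.abs(x[:, None] - rec_xy[None, :, 0]), axis=1)
                det_t, det_r = t, nearest
            else:
                d50 = scn.detection_d50 * (
                    1.0 + scn.tide_detection_coef * (height - tide_mean_obs)
                )
                dist = np.abs(x[:, None] - rec_xy[None, :, 0])
                p = 1.0 / (1.0 + np.exp((dist - d50[:, None]) / scn.detection_shape))
                hits = rng.uniform(size=p.shape) < p
                det_idx, det_rec = np.nonzero(hits)
                det_t, det_r = t[det_idx], det_rec
            if len(det_t):
                all_ts.append(det_t)
                all_tag.append(np.full(len(det_t), tag.tag_id, dtype=object))
                all_rec.append(
                    np.array([f"R{r + 1}" for r in det_r], dtype=object)
                )
        departure_day[tag.tag_id] = None if departed is None else str(departed.date())

    if all_ts:
        det = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(
                    np.round(np.concatenate(all_ts) * 1e3).astype("int64"), unit="ms"
                ),
                "tag_id": np.concatenate(all_tag),
                "receiver_id": np.concatenate(all_rec),
            }
        ).sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    else:
        det = pd.DataFrame(columns=["timestamp", "tag_id", "receiver_id"])

    truth = {
        "scenario": {
            k: (v if not isinstance(v, (dict, tuple)) else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(scn).items()
            if not isinstance(v, (dt.date,))
        },
        "study_start": str(scn.study_start),
        "study_end": str(scn.study_end),
        "q_month": {str(k): v for k, v in scn.q_month.items()},
        "peak_month": int(max(scn.q_month, key=scn.q_month.get)),
        "departure_day": departure_day,
        "sexes": {t.tag_id: t.sex for t in tags},
    }
    return SimResult(
        detections=det,
        receivers=receivers,
        tags=tags,
        tide_extremes=extremes,
        sst=sst,
        water=scn.water_polygon(),
        truth=truth,
        config=config,
    )


def write_outputs(result: SimResult, outdir) -> dict:
    """Write the simulated dataset in exactly the formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .io import write_detections

    paths = {
        "detections": outdir / "detections.csv",
        "receivers": outdir / "receivers.csv",
        "tags": outdir / "tags.csv",
        "tide": outdir / "tide_extremes.csv",
        "sst": outdir / "sst.csv",
        "water": outdir / "water.geojson",
        "truth": outdir / "truth.json",
    }
    write_detections(result.detections, paths["detections"])
    pd.DataFrame(
        [
            {
                "receiver_id": r.receiver_id,
                "x": r.x,
                "y": r.y,
                "deploy_date": r.deploy_date,
                "recover_date": r.recover_date,
                "status": r.status,
            }
            for r in result.receivers
        ]
    ).to_csv(paths["receivers"], index=False)
    pd.DataFrame(
        [
            {
                "tag_id": t.tag_id,
                "sex": t.sex,
                "total_length": t.total_length,
                "tagging_date": t.tagging_date,
                "emission_min": t.emission_min,
                "emission_max": t.emission_max,
            }
            for t in result.tags
        ]
    ).to_csv(paths["tags"], index=False)
    pd.DataFrame(
        [
            {"time": e.time.isoformat(), "height": f"{e.height:.4f}", "kind": e.kind}
            for e in result.tide_extremes
        ]
    ).to_csv(paths["tide"], index=False)
    sst = result.sst.rename("sst_c").rename_axis("date").reset_index()
    sst["date"] = sst["date"].dt.strftime("%Y-%m-%d")
    sst["sst_c"] = sst["sst_c"].map(lambda v: f"{v:.4f}")
    sst.to_csv(paths["sst"], index=False)
    paths["water"].write_text(
        json.dumps(shapely.geometry.mapping(result.water), sort_keys=True)
    )
    paths["truth"].write_text(json.dumps(result.truth, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
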