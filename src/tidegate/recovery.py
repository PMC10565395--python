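"""Parameter-recovery experiments: simulate, run the pipeline, compare to truth.

The report pits pipeline estimates against the generator's truth record:

* monthly occupancy: the mean daily detected/remaining proportion per month
  against the latent q(month), and the recovered peak month;
* seasonality model: the cyclic month smooth's peak month, and the AICc
  support for a sex-by-month interaction (positive values favour it);
* departure timing: per-sex spread of final-detection days (abrupt male
  exits compress the male spread);
* intra-day tide effect: sign of the male high-vs-low tide-height contrast
  from the intra-day model.

Every assertion a caller makes should read latent values from
``report["truth"]`` only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import curation, residency, tables, tides
from .gam import BinomialGAM, ModelSpec, Smooth
from .simulate import SimScenario, SimResult, simulate

__all__ = ["null_scenario", "run_recovery"]


def null_scenario(base: SimScenario) -> SimScenario:
    """The matched no-sex-difference control: males behave like females."""
    import dataclasses

    return dataclasses.replace(
        base,
        q_month_male=None,
        male_departure_hazard=base.female_departure_hazard,
        male_departure_months=tuple(range(1, 13)),
        male_mean_position=base.female_mean_position,
        male_tide_drift=0.0,
    )


def _fit_seasonal_pair(seasonal: pd.DataFrame, df: int = 5, maxfev: int | None = None):
    month = Smooth("month", basis="cc", df=df, bounds=(0.5, 12.5))
    month_by = Smooth("month", basis="cc", df=df, bounds=(0.5, 12.5), by="sex")
    with_ix = ModelSpec(
        "sex_month", "detected", (month, month_by), ("sex",), random="tag"
    )
    without = ModelSpec("month_only", "detected", (month,), ("sex",), random="tag")
    fit_with = BinomialGAM(with_ix, seasonal).fit(maxfev=maxfev)
    fit_without = BinomialGAM(without, seasonal).fit(maxfev=maxfev)
    return fit_with, fit_without


def run_recovery(
    scenario: SimScenario,
    df: int = 5,
    maxfev: int | None = None,
    fit_intraday: bool = False,
) -> dict:
    """Simulate one scenario and report pipeline estimates next to the truth."""
    res: SimResult = simulate(scenario)
    config = res.config
    cur, report = curation.curate(
        res.detections, config, tagging_days=sorted({t.tagging_date for t in res.tags})
    )
    p = residency.build_presence(cur, config)
    rp = residency.remaining_proportion(p)
    monthly = rp["proportion"].groupby(rp.index.month).mean()

    amp = tides.daily_amplitude(res.tide_extremes)
    seasonal = tables.build_seasonal_table(p, res.tags, sst=res.sst, tide_amplitude=amp)
    fit_with, fit_without = _fit_seasonal_pair(seasonal, df=df, maxfev=maxfev)
    grid = np.arange(1, 13)
    smooth = fit_without.smooth_values("s(month)", grid)
    peak_month = int(grid[int(np.argmax(smooth))])
    delta_aicc_sex_month = fit_without.aicc - fit_with.aicc

    # departure timing spread per sex (days between earliest and latest final
    # detection among tags that left before the study end)
    last_day = {
        t: p.presence.index[p.presence[t]][-1]
        for t in p.tags
        if p.presence[t].any()
    }
    sexes = res.truth["sexes"]
    spread = {}
    for sex in ("female", "male"):
        lasts = [d for t, d in last_day.items() if sexes.get(t) == sex]
        if lasts:
            spread[sex] = float((max(lasts) - min(lasts)).days)

    out = {
        "monthly_occupancy": {int(m): float(v) for m, v in monthly.items()},
        "peak_month": peak_month,
        "month_smooth": {int(m): float(v) for m, v in zip(grid, smooth)},
        "delta_aicc_sex_month": float(delta_aicc_sex_month),
        "departure_spread_days": spread,
        "n_curated": int(len(cur)),
        "n_analyzed": int(sum(p.presence[t].any() for t in p.tags)),
        "truth": res.truth,
    }

    if fit_intraday:
        tide = tides.build_tide_series(res.tide_extremes)
        intraday = tables.build_intraday_table(cur, p, res.tags, tide=tide)
        spec = ModelSpec(
            "tide_sex",
            "detected",
            (),
            ("sex", "tide_height_class", "tide_height_class:sex"),
            random="tag",
        )
        fit = BinomialGAM(spec, intraday).fit(maxfev=maxfev)
        rows = {}
        for sex in ("female", "male"):
            probe = pd.DataFrame(
                {
                    "sex": sex,
                    "tide_height_class": ["low", "intermediate", "high"],
                    "tag_id": intraday["tag_id"].iloc[0],
                }
            )
            eta = fit.predict(probe, linear=True)
            rows[sex] = {
                "low": float(eta[0]),
                "intermediate": float(eta[1]),
                "high": float(eta[2]),
            }
        out["tide_height_effect"] = rows
        out["male_high_minus_low"] = rows["male"]["high"] - rows["male"]["low"]
        out["female_high_minus_low"] = rows["female"]["high"] - rows["female"]["low"]
    return out
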