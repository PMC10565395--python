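# tidegate

Passive acoustic telemetry analysis for **gate arrays in tidal inlets**:
residency and roaming statistics, tide covariates, circular hour-of-day
tests, penalized binomial GAMs with AICc ranking, and water-masked dynamic
Brownian bridge space use — plus a synthetic telemetry simulator for
end-to-end parameter-recovery testing.

The package is written for movement ecologists working with coded acoustic
transmitters (e.g. large coastal sharks) monitored by a line of receivers
spanning a narrow inlet, where each receiver acts as a detection "gate"
and the tide dominates within-day dynamics.

## What it computes

From curated detections (collision proxy, daily-singleton removal, tagging
window, non-representative tags) the seasonal arm derives, per individual:

- **minimum residency** `= days detected / study duration` and
  **maximum residency** `= days detected / (last − first detection day + 1)`,
  which bracket the true residency;
- **roaming index** `= mean over present days of (receivers visited / R)`,
  in `[1/R, 1]` for an R-receiver array;
- residency **categories** (vagrant `< 0.1`, short-term `0.1–0.5`,
  long-term `> 0.5` on minimum residency), presence/absence **bouts**, and
  daily **detected/remaining proportions** (a departure-corrected abundance
  index, also per sex);
- binomial GAMs of daily detection and of roaming
  (`logit E[y] = sex + s(TL) + s(month) + s(month):sex + s(SST) + s(tide amplitude)
  + tag`, cyclic splines for month, random intercepts per tag), ranked by
  `AICc = AIC + 2k(k+1)/(n−k−1)`;
- dynamic Brownian bridge utilization distributions masked to the water
  polygon, 50% contour areas and directed between-group overlap.

The intra-day arm maps detection times to angles on the 24 h circle, runs
Rao's spacing test (Monte-Carlo p-values) per individual and Rao's
homogeneity test across individuals, clusters hourly profiles (UPGMA), and
models hourly detection against tide height / direction / strength classes
built from cosine-interpolated tide extremes.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
import datetime as dt
from tidegate.simulate import SimScenario, simulate
from tidegate import curation, residency

scenario = SimScenario(
    study_start=dt.date(2019, 11, 1),
    study_end=dt.date(2020, 4, 30),
    n_females=4, n_males=3, seed=42,
)
result = simulate(scenario)

curated, report = curation.curate(
    result.detections, result.config,
    tagging_days=sorted({t.tagging_date for t in result.tags}),
)
presence = residency.build_presence(curated, result.config)
for rec in residency.residency_indices(presence, n_receivers=5):
    print(f"{rec.tag_id}: days={rec.days_detected:3d} "
          f"min={rec.min_residency:.3f} max={rec.max_residency:.3f} "
          f"roaming={rec.roaming:.3f} {rec.category}")
```

prints

```
F01: days=118 min=0.652 max=0.656 roaming=0.631 long-term
F02: days=101 min=0.558 max=0.701 roaming=0.628 long-term
F03: days= 65 min=0.359 max=0.942 roaming=0.637 short-term
F04: days= 57 min=0.315 max=0.919 roaming=0.639 short-term
M01: days= 66 min=0.365 max=0.667 roaming=0.555 short-term
M02: days= 75 min=0.414 max=0.735 roaming=0.536 short-term
M03: days= 63 min=0.348 max=0.663 roaming=0.524 short-term
```

Each line brackets an individual's residency (e.g. F03 was detected on 65
of the 181 study days — minimum residency 0.359 — but on 94% of the days
between its first and last detection, so it is a short-term resident with
gappy but intense use of the inlet) and summarises its within-array
mobility (roaming ≈ 0.63 means it visited on average about three of the
five gates per present day).

The same dataset drives the model stages:

```python
from tidegate import tables, tides
from tidegate.gam import BinomialGAM
amp = tides.daily_amplitude(result.tide_extremes)
seasonal = tables.build_seasonal_table(presence, result.tags,
                                       sst=result.sst, tide_amplitude=amp)
fit = BinomialGAM(tables.seasonal_candidates()[1], seasonal).fit()
print(fit.summary())
```

A command-line front end mirrors the library:
`tidegate simulate`, `curate`, `tides`, `run-seasonal`, `run-intraday`
(each arm writes its artifacts plus a `manifest.json` whose content hash is
reproducible for a given input, config and seed).

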