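# Methods

`tidegate` analyses passive acoustic telemetry from a "gate" array — a line
of omnidirectional receivers spanning a narrow tidal inlet, so that an
animal passing a receiver is assumed detectable across the channel width.
The pipeline has two arms: a *seasonal* arm (daily presence, residency and
roaming statistics, detection/roaming models, space use) and an *intra-day*
arm (hour-of-day circular statistics and tide-covariate models).  This note
records the models, the conventions they rest on, and the choices made
where the procedure was genuinely open.

## Time conventions

All daily statistics depend on where the day boundary falls.  Raw
timestamps are treated as UTC and shifted by a configurable offset
(default −3 h, Argentina) before truncation to a local day; the same
convention feeds the hour-of-day analyses.  The scalar *study duration* is
the exclusive difference `study_end − study_start` in days (497 days for a
window from 2019‑11‑01 to 2021‑03‑12), because that is the convention under
which the published duration is reproduced.  The day *axis* of the presence
matrix includes both endpoints (498 monitored days for that window).

## Curation

Four filters run in a fixed order; reordering changes the daily-singleton
counts, and a property test asserts the order:

1. **Collision proxy.** Receivers cannot log true code collisions, so any
   detection with another detection of a *different* tag at the *same*
   receiver within a strict window (default 1 s) is removed; exact
   duplicate rows collapse to one copy.  A window of 0 disables the proxy.
2. **Daily singletons.** A lone detection of a tag at a receiver within one
   local day is a likely false detection and is removed; groups of ≥ 2 are
   kept whole.
3. **Tagging window.** All detections on the (configurable) tagging days
   are dropped to avoid post-tagging stress artefacts.
4. **Non-representative tags.** A tag whose entire history falls within the
   first `horizon_days` (default 5) days of the study is excluded; the
   horizon is measured from the study start, not per-tag tagging dates.

Tags that sit at a single receiver for ≥ 30 consecutive days with no gap
longer than one day are *flagged* as likely tag loss/expulsion but excluded
only on request — that decision is an inspection call, not an automatic
rule.

## Residency, roaming, bouts, remaining proportions

From the daily presence matrix (tag × local day, with the set of receivers
visited per day):

- **Maximum residency** = days detected / inclusive first-to-last span.
- **Minimum residency** = days detected / fixed study duration.  Because
  the duration is exclusive while the span is inclusive, a tag spanning the
  entire window would get min > max; the minimum-residency denominator is
  therefore floored at the tag's span, which only differs in that
  degenerate case and restores min ≤ max with equality exactly for a
  full-span tag.
- **Roaming index** = mean over present days of (receivers visited / R);
  with R = 5 active receivers it lives in [0.2, 1].
- **Categories** on minimum residency: vagrant < 0.1, short-term 0.1–0.5
  (both boundaries closed), long-term > 0.5.
- **Bouts**: run-length encoding of each tag's presence vector restricted
  to [first, last] detection day; presence and absence bouts alternate and
  sum to the span.
- **Detected/remaining proportion**: per day, tags detected divided by tags
  whose final detection is on or after that day (a tag leaves the
  denominator the day *after* its last detection); an empty denominator
  yields a missing value, never 0.  Per-sex variants (`prop_f`, `prop_m`)
  feed the roaming model.

## Tide covariates

Astronomic predictions arrive as alternating high/low extremes.  Heights
between consecutive extremes follow the standard cosine interpolant sampled
hourly; gaps over 15 h are rejected.  Daily amplitude is max(high) −
min(low) among a local day's extremes (missing if either kind is absent).
Hourly classes:

- **height**: low / intermediate / high at the 0.25 and 0.75 empirical
  quantiles of the full hourly series.  The quantile estimator is fixed to
  linear interpolation (numpy default, "type 7") because the class
  boundaries depend on it.  A degenerate constant series is all
  intermediate.
- **direction**: inflow while rising, outflow while falling; a zero hourly
  difference inherits the previous hour's label.
- **strength**: *weak* when |height − height of the nearest extreme| is
  below a threshold (default 0.5 m — the neighbourhood of slack), else
  *strong*.  The threshold is strict (= 0.5 m is strong) and configurable.

Optional calibration against in-situ logger data fits
`logger ≈ offset + scale·predicted(t − lag)` with the lag grid-searched
over ±120 min in 5-min steps and offset/scale by least squares; all three
parameters are reported together with the RMSE, and applying the
calibration transforms the predicted series.

## Circular statistics

Detection times map to angles (360° per 24 h of local time).  **Rao's
spacing test** uses U = ½ Σ|Tᵢ − 360/n| over the sorted arc gaps including
the wrap-around gap.  P-values are Monte-Carlo: the share of seeded uniform
samples of the same size with U ≥ observed (default 10 000 reps).  The null
gaps are drawn directly as normalised exponential spacings (the exact joint
law of circular gaps), which avoids sorting and keeps large samples cheap.
The coarse published critical-value tables are not embedded; the MC null is
the reference, cross-checked in tests against its own convergence.

**Rao's homogeneity test** compares polar vectors across individuals: for
each sample the tangent of the mean direction and the mean resultant
length, with delta-method variances; each component is a weighted one-way
chi-square on k − 1 d.f., and the combined statistic sums both (2(k − 1)
d.f.).  The tangent statistic is undefined near ±90° mean directions and
blind to exactly antipodal means — a classical property of the test, noted
in the API docs.

Hourly profiles (per-tag 24-vectors of detection proportions) are clustered
with average linkage (UPGMA) on Euclidean distance; the linkage is the
published choice, the metric is ours.

## Binomial GAMs

Three tables feed penalized binomial additive models: daily detection (0/1
per tag-day through each tag's last detection), roaming (receivers visited
out of R on present days, a binomial count response), and hourly detection
(0/1 per tag-hour on present days, with tide covariates joined by hour).

The engine is penalized IRLS over a design of: intercept; categorical
terms (including `a:b` interactions); cubic **P-splines** (equally spaced
B-spline basis, second-order difference penalty) for aperiodic covariates;
**cyclic cubic regression splines** (coefficients are function values at
knots, exact integrated-squared-curvature penalty, function and first two
derivatives matching at the period ends) for month and hour; and per-tag
**random intercepts** as ridge-penalized dummy blocks — the standard
GAMM-as-GAM device, with `tag:sex` stratifying the ridge block and its
smoothing parameter by sex.  Temperature uses a non-cyclic basis by
default: it is seasonal but not inherently periodic, and the choice is a
config switch.

Smoothing parameters minimise the UBRE/GCV score `deviance/n + 2·edf/n`
(binomial scale fixed at 1) by Nelder–Mead on the log scale with a wide
initial simplex; the inner PIRLS warm-starts between evaluations.
Effective degrees of freedom are tr[(XᵀWX + S)⁻¹XᵀWX], reported per term.
Model ranking uses AICc = AIC + 2k(k+1)/(n − k − 1) with k = total
effective parameters and n = table rows.  AICc values are backend-specific
(they depend on the basis dimensions and the smoothing-parameter criterion),
so candidate sets are compared by *ranking and recovery behaviour*, never
against printed values from other software; an mgcv fit serves as an
independent oracle for the fitted curves in the test suite.  A second-order
difference penalty cannot shrink a smooth's linear component, so an
uninformative covariate bottoms out near 1 effective d.f. (its penalty null
space), which is what the penalization test asserts.  Constant-response
fits are flagged degenerate and excluded from ranking.

## Space use (dynamic Brownian bridge)

Tracks use the study's rules: consecutive detections at different receivers
joined when 5 min ≤ gap ≤ 24 h; silence > 24 h starts a new track; a
different-receiver switch under 5 min is implausible transit and also
breaks the track; same-receiver runs collapse to their first/last fixes.

The motion variance σ²ₘ is the dynamic estimator: within sliding windows
(default 31 fixes, margin 11 — conventional defaults, configurable) the
leave-one-out bridge likelihood of interior fixes is maximised; short
tracks fall back to one track-wide MLE.

The utilization distribution integrates two kinds of segment:

- **stationary segments** (both endpoint fixes at the same receiver): the
  animal's location is a single point observed with error δ, so the
  segment contributes N(position, δ²I) weighted by its duration.  Under
  this convention a stationary cluster's 50% contour area equals the
  analytic 2π·ln 2·δ², which the tests verify to discretisation error.
  (Time-integrating a zero-displacement *bridge* instead would mix
  variances between δ²/2 and δ² — an interpolation artefact for an animal
  that is not moving.)
- **moving bridges**: Gaussian with mean a + τ(b − a) and variance
  τ(1 − τ)Tσ²ₘ + (1 − τ)²δ² + τ²δ², time-integrated with an adaptive
  number of substeps (kernel spacing at most half the narrowest bridge
  width) and weighted by T.

δ defaults to 200 m — half the array's nominal effective detection range —
and the grid cell to 50 m (the inlet is a few hundred metres wide); both
are configurable, and the 50% contour areas react to them, so between-group
*overlap percentages* are the robust comparison, not absolute areas.
Bridges whose straight chord crosses land are re-routed along the shortest
in-water path (visibility graph over the water polygon's vertices) with
time allocated by path-length fraction.  The accumulated density is masked
to water cells and renormalized; the 50% contour is the smallest
highest-density cell set holding half the mass (ties broken by cell index
for determinism), and overlap between groups is directed:
area(a∩b)/area(a).

Group surfaces pool bridge contributions across individuals weighted by
tracked time.

## Synthetic data generator

The simulator emulates the study conditions so every stage is testable
without field data: a 15 km × 400 m inlet with five receivers 2 km apart in
its upper half; 18 tags (11 female, 7 male); transmissions at uniform
60–180 s intervals; logistic distance detection p(d) = 1/(1 + exp((d −
d₅₀)/s)) with d₅₀ = 250 m, s = 50 m (effective range a few hundred metres),
optionally modulated by tide height; semidiurnal tides at the M2 period
(12.42 h) with a spring–neap envelope; SST = 13 + 5·cos(2π(doy − 46)/365.25)
°C (max 18 °C mid-February, min 8 °C mid-August).

Daily presence is Bernoulli with a monthly occupancy curve peaking in
December (0.90) and bottoming in June–July (0.10).  Males use the square of
the female curve — the same peak with a sharper seasonal contrast — and
carry a high daily departure hazard (0.12/d) confined to February–March, so
most exit abruptly late in the high season; females taper with a small
year-round hazard (0.008/d).  Departure is permanent.  Within the inlet,
position follows an Ornstein–Uhlenbeck process along the axis (8 h
relaxation, 2 km equilibrium SD, exact transition sampling via a scaled
cumulative sum; the tide-dependent mean is applied quasi-statically).  The
male mean sits at the array's lower edge and drifts up-inlet with tide
height (1500 m per metre of height deviation), which realises both "drift
toward the upper flats at high tide" and a male-only high-tide detection
gain.  A side effect of this mechanism is partial spatial segregation of
the sexes in the default scenario's space-use surfaces; scenarios probing
space-use overlap should place the sexes at a common mean.

What the generator does **not** emulate: receiver outages and detection
interference (collisions are produced only by chance coincidence),
tag-induced mortality, within-day behavioural bouts beyond OU
autocorrelation, cross-inlet (y) movement, and hydrodynamics.  Passing
recovery tests therefore shows the pipeline recovers the *statistical
structure it assumes*, not that field data meet those assumptions.

Every latent parameter and per-tag departure day is written to
`truth.json`; recovery assertions read latent values only from there.  With
a fixed seed, outputs are byte-identical.

### Problem sizes

The test suite and the acceptance script run scaled-down scenarios chosen
to exercise every code path at sound statistical power: recovery
experiments use one simulated year with the full 18-tag array (seasonal
GAM pairs fit in seconds), fixture scenarios use 2–5 tags over 1–3 months,
and Monte-Carlo calibrations use 10⁴ replicates.  The defaults in
`SimScenario` keep the full two-high-season study window for users who want
the paper-scale configuration.

## Numerical choices and degenerate inputs

- Binomial means are clipped to [1e−10, 1 − 1e−10]; PIRLS adds a 1e−9
  ridge jitter before each solve.
- Quantile class boundaries: `h ≤ q25` low, `h ≥ q75` high; if q25 = q75
  every hour is intermediate.
- Contour ties break by flat cell index; UD mass is renormalized after
  masking, and a fully-masked surface is an error rather than a silent
  zero.
- Empty detection tables propagate as empty results through curation and
  presence building; zero-detection tags are omitted from residency
  records and hourly profiles.
- The collision window, slack threshold, category boundaries and track gap
  rules are all strict/closed exactly as documented above, and each has a
  boundary test.

## Known limitations

- The homogeneity test inherits the tangent statistic's antipodal blind
  spot; strongly bimodal hourly patterns can defeat it.
- AICc uses table rows as n; for the binomial-count roaming response an
  argument could be made for total trials instead.  Ranking is insensitive
  to this choice within a candidate set (n is common), but cross-table
  AICc values are not comparable.
- The visibility-graph router assumes the water polygon is a single simple
  polygon; multi-part inlets need a pre-merged geometry.
- ESRI shapefiles are not read; supply GeoJSON or WKT.
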