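# Methods

## Scope and data model

The package reconstructs two analysis chains around an inlet spawning-site
telemetry study and an estuary-wide haul-seine survey. All tables are pandas
DataFrames in plain CSV; timestamps are naive local civil time in fixed-offset
Eastern Standard Time (UTC−5, no daylight-saving transitions), so hourly
binning is reproducible on any platform. Coordinates are planar meters; no
geodesy is attempted.

## Telemetry processing

**Spurious-detection filter.** A lone detection of a transmitter code in the
core array (receivers 3–19) within a 24 h period is treated as a code
collision and removed. "24 h period" defaults to the local calendar day — the
daily scale on which everything downstream is reported — with a rolling
±24 h neighbourhood available as an option. The filter and the 48 h
post-release split are conservation-checked: kept ∪ removed always equals the
input exactly.

**Censoring.** Detections after a tag's censor date (mortality or tag loss)
are dropped; the censor date itself is retained, treating it as the last day
the fish was considered alive. `flag_stationary` surfaces candidate censor
dates (runs of ≥ `min_days` consecutive detected days confined to
≤ `receiver_spread` adjacent receivers) but deliberately does not apply them:
the mortality call stays with the analyst.

**Positioning.** Hourly weighted-means positions: each detection contributes
one unit of weight at its receiver, so a bin's position is the
detection-count-weighted mean of receiver coordinates, and the mean receiver
number is the same weighting applied to receiver ids. Bins are clock-aligned
half-open intervals `[HH:00, HH+1:00)`. Positions are translation-equivariant
and always lie in the convex hull of the contributing receivers. Zone
assignment uses the zone polygon containing the position, with ambiguous
points (shared boundaries, outside all polygons) resolved to the nearest zone
centroid; without polygons the nearest receiver's zone is used. The control-tag
audit reports easting error (the channel axis, where the array resolves
position), the full Euclidean error alongside, and a detection rate defined as
detections logged by the receiver nearest the control tag divided by the
transmissions expected from its fixed 60 s delay.

## Residence metrics

Per fish, year, and scope (whole array vs spawning site, zones 2–3): DD =
distinct detection dates, TP = (last − first) + 1 days (both endpoints
counted — this convention reproduces every printed value in the packaged
reference table, e.g. 4 June → 19 Aug = 77 d), RI = 100·DD/TP rounded to one
decimal for display. RI is conventionally reported for fish detected on at
least five dates; the packaged table prints RI for smaller DD too, so the
eligibility flag is attached rather than enforced. For the correlation between
whole-array and spawning-site RI the default eligibility threshold is
DD_SS ≥ 4, which reproduces the reference pairing of n = 38 fish-years
(a threshold of 5 gives 37 pairs and changes r by < 0.005; both r ≈ 0.906).

The Mann-Whitney U (scipy, midrank ties, asymptotic two-sided p) and the
goodness-of-fit χ² accept user-supplied expected proportions because
monitoring effort differs between zones; with equal expected counts the χ² of
the reference zone totals does not reproduce the historically reported value,
whose expected-count convention is unrecorded.

## Lunar phase

Mean-synodic approximation: 360 × (days since the reference new moon of
2000-01-06 18:14 UTC, modulo 29.530588853 d) / 29.530588853, supported
1990–2050. Date-level inputs are evaluated at local noon, the representative
instant of a civil day. Checked against almanac new-moon dates for 2007–2009,
the approximation stays within ±12° — ample for a 0–360° covariate entering a
cyclic smooth.

## Presence model

Daily presence records: one row per active, uncensored tag per
spawning-season date (April–September); present = 1 iff at least one hourly
position fell in zones 2–3 with bin start in [14:00, 20:00). Fish-day
granularity was chosen because tags duty-cycle and fish leave receiver range
within days; a fish-hour option would mostly add serially dependent zeros.

The model is a penalized binomial GLM in mixed-model form: fixed effects
(intercept, male–female contrast, sex-specific linear slopes of centered body
size), two cyclic cubic regression splines, and a per-fish random intercept
as a ridge-penalized block. The cyclic basis is parameterized by function
values at k evenly spaced knots with the integrated-squared-second-derivative
penalty in closed form (D'B⁻¹D); a sum-to-zero constraint is absorbed by a QR
reparameterization, leaving each smooth's penalty full-rank so the smoothing
parameter alone controls shrinkage to zero. Defaults: 10 knots for day of
year (period 365.25, keeping multi-year phases aligned), 8 for lunar phase
(period 360) — generous for one seasonal peak and a semi-lunar cycle;
knot-count sensitivity is negligible in the recovery studies.

Inner fits are penalized IRLS (Newton with step halving on the penalized
Bernoulli log-likelihood, convergence 1e-9 relative). Smoothing parameters
and the random-intercept precision are selected by Laplace-approximate
marginal likelihood, optimized by Nelder-Mead over the three log-parameters
with a wide initial simplex (step 4 in log-space) so the search reaches the
heavy-shrinkage regime a null smooth requires. Per-term effective degrees of
freedom are block traces of (X'WX+S)⁻¹X'WX; term p-values are approximate
Wald tests on the Bayesian posterior covariance with df = max(1, round(edf))
for smooths — adequate for the direction/significance reporting the model is
used for, and conservative under the null (edf → 0, p → 1). A
complete-separation heuristic flags unpenalized coefficients beyond ±15
logits. The whole fit is cross-validated against mgcv's `gam` (cc splines,
`bs="re"` random effect, REML) in the test suite: on a common simulated
dataset the sex coefficient agrees to < 0.001 and smooth curves to < 0.03
logits.

Population-level predictions set the random effect to zero; `smooth_curve`
returns each centered smooth with pointwise SEs, and `plot_smooths` draws
them.

## CPUE standardization

**Region classification.** A weighted 2-D Gaussian KDE with a fixed isotropic
bandwidth (absolute survey units; default two grid widths) over haul
locations weighted by nominal CPUE; the density threshold enclosing
`contour_level` (default 0.5) of the total mass on an 80×80 evaluation grid
defines the concentrated contour, and survey grids whose centers exceed it
are labelled concentrated. The KDE is computed directly rather than with a
covariance-scaled estimator because the classification needs a bandwidth in
meters that does not depend on the survey footprint and must tolerate
collinear point sets. An unweighted variant (positive-catch locations only)
is a flag; bandwidth and contour level are recorded in the output metadata.

**Hurdle model.** Presence: binomial GLM with logit link (statsmodels).
Positive catch: OLS on log counts. Forward stepwise AIC from year-only, both
sub-models independently; candidates are year (always retained), month,
region, season, region×season (eligible only when both mains are in), 2.5°C
temperature bins, 2.5‰ salinity bins (half-open `[k·w, (k+1)·w)`, labels at
midpoints), and vegetation. Month and season are aliased by construction, so
whichever enters first blocks the other. Terms whose fit fails (separation,
singular design) are dropped with a warning.

**Index.** Year-specific marginal means on the link scale average the linear
predictor over a balanced grid (equal weight per combination of the other
included factors' observed levels); the SE comes from the coefficient
covariance and the df is the sub-model's residual df (capped at 200 in the
Monte Carlo, effectively normal). Per year, 10,000 Student-t realizations
around each marginal mean are back-transformed — inverse logit for presence,
exp(t + σ̂²/2) for the positive part, with the lognormal half-variance
correction toggleable to a naive exp — and multiplied. The index is therefore
a back-transformed link-scale marginal mean, not a population mean; the
ranking study defines truth on the same estimand. With a fixed seed the draws
are bit-reproducible.

## Synthetic data

**Telemetry.** A 42-receiver array mirroring the inlet layout: 17 core
receivers at 100 m spacing along the beach (zones 2–3), Gulf-side receivers
(zone 1), a transit corridor (zone 4), a northern refuge containing receiver
23 (zone 7), and estuary interior lines (zones 5–6), with rectangular zone
polygons and three fixed 60 s control tags (one midway between receivers 9
and 10). Daily presence at the site follows the logistic process of the
presence model; defaults encode the study conditions: baseline −1.2, seasonal
amplitude 1.5 peaking at day 182, semi-lunar amplitude 0.8 (maxima at new and
full moon), sex effect +1.0 (M−F), random-intercept SD 0.8. Present fish
visit the site through the 1400–2000 h window around a per-day core-array
anchor and hold near the refuge before and after; 35% of absent days are
refuge-only array visits (so whole-array residence exceeds site residence, as
in real arrays); otherwise the fish is out of range. The within-day track is
a two-state stand-in — it reproduces daily-scale site/refuge structure, not
within-day movement rates, which are unquantified. Pings follow each tag
model's uniform inter-pulse delay (V9 15–45 s, 149 d battery; V13 30–90 s,
duty-cycled 22 Mar–20 Sep for three seasons) as Poisson hourly counts;
detection is Bernoulli per transmission per receiver with a logistic distance
kernel, p = 1/(1+exp(s·(d−85))) with slope s = 0.05 m⁻¹ — the 50% range is a
measured study condition, the slope a free parameter. Per-receiver counts
given the hourly ping count are exact binomials, sampled as such for speed.
Stray single detections are injected at 0.02 per tag-day. Each fish draws
from an independent stream spawned from the master seed, so adding a fish
never perturbs the others.

**Survey.** Stratified-random hauls over a grid with two CPUE hotspots;
presence depends on year, true region, spawning season, and binned
temperature; positive catches are lognormal in year, region, and vegetation;
salinity is generated but carries no effect, a deliberate decoy for selection
tests. The presence intercept (−1.55) targets the documented survey-wide
positive-haul fraction of about one third. Counts are `max(1, round(·))` of
the lognormal draw — at low mean catch this discretization inflates the log
scale, which is why the index-ranking study raises the positive mean to ~12
fish per successful haul.

**What the generators do not emulate** (so what passing tests do not show):
tidal-current-dependent detection efficiency, transmitter collisions,
within-day movement dynamics, spatial autocorrelation of hauls beyond the
hotspot structure, and observation error in covariates. Recovery results
certify the estimation chain under the assumed generating process, not the
field performance of the original array.

## Simulation studies (`spawntrack.studies`)

Problem sizes were chosen so Monte-Carlo error is small relative to each
property: presence recovery runs the full detection pipeline (simulate →
filter → position → records → fit) for 40 fish over a 150 d season, 20
replicates — the seed-averaged sex contrast lands within a few hundredths of
truth, the seasonal peak within a few days, and detection-derived presence
agrees with true presence on > 99% of fish-days. The null-lunar calibration
(50 replicates of 30 fish) fits records drawn directly from the daily
logistic process, since the detection layer is already validated; the lunar
edf collapses toward zero and p > 0.05 in essentially all replicates. The
survey studies use 20 replicates of 5–6 year surveys with a few hundred hauls
per year: with a region effect present, forward AIC retains region and
excludes the temperature/salinity decoys in ≥ 90% of replicates, and the
index reproduces the true year ranking in every replicate with a systematic
ratio bias of ~3%. Under a fully null survey, forward AIC keeps both
sub-models year-only in only ~20% of replicates — the expected behaviour of
AIC-based forward selection, which admits a spurious d-df term with
probability P(χ²_d > 2d) ≈ 0.16 at 1 df; this is a property of the selection
rule itself, documented here rather than "fixed", since changing the rule
(e.g. to BIC) would change the method.

## Known limitations

- Smooth-term p-values are approximate Wald tests; they are calibrated well
  enough for direction/significance statements, not for fine-grained
  inference near p ≈ 0.05.
- The lunar covariate is a mean-synodic phase, not an ephemeris; errors up to
  ~12° are absorbed by the lunar smooth.
- The marginal-means reference grid weights every observed factor-level
  combination equally; with severely unbalanced surveys a model-weighted grid
  could be preferable but is not implemented.
- The detection kernel's slope and the within-day track model are synthetic
  conventions; analyses of real arrays should range-test their own geometry.
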