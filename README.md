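# spawntrack

Tools for two workhorse analyses in coastal fish reproductive ecology, built
around an estuarine inlet spawning-site study of Common Snook (*Centropomus
undecimalis*) in Tampa Bay:

1. **Passive acoustic telemetry.** Raw receiver detections are filtered
   (spurious single detections, a 48 h post-release acclimation window,
   dead-tag truncation), collapsed to hourly weighted-means positions on two
   location scales (planar coordinates and receiver number), assigned to
   monitoring zones, and summarised as residence metrics: days detected (DD),
   total period from first to last detection (TP, counting both endpoints),
   and the residence index RI = 100·DD/TP for the whole array and for the
   spawning site (zones 2–3). Daily presence at the site during the
   spawning window (1400–2000 h, April–September) is then modelled with a
   **binomial additive mixed model**

   logit P(present<sub>ij</sub>) = β<sub>sex</sub> + β<sub>size·sex</sub> +
   f<sub>doy</sub>(day of year) + f<sub>lunar</sub>(lunar phase) + u<sub>i</sub>,
   u<sub>i</sub> ~ N(0, σ²)

   where f<sub>doy</sub> and f<sub>lunar</sub> are cyclic cubic regression
   splines (periods 365.25 d and 360°; new moon at 0/360, full moon at 180)
   and u<sub>i</sub> is a per-fish random intercept. The penalized fit selects
   smoothing parameters and the random-effect variance by Laplace-approximate
   marginal likelihood; the implementation is validated against `mgcv` in the
   test suite.

2. **Haul-seine CPUE standardization.** Zero-inflated survey catch rates are
   standardized with a delta-lognormal hurdle model: survey grids are
   classified into concentrated/not regions by a CPUE-weighted kernel density
   contour; a binomial (logit) presence sub-model and a lognormal
   positive-catch sub-model are each selected by forward stepwise AIC from
   {year, month, region, season, region×season, 2.5°-binned temperature,
   2.5‰-binned salinity, vegetation} with year always retained; year-specific
   marginal means (balanced over the other included factors, on the link
   scales) are combined by Monte Carlo — 10,000 Student-t realizations per
   sub-model, back-transformed (inverse logit; exp(·+σ̂²/2)) and multiplied —
   into an annual index distribution.

A first-class synthetic-data module generates both data streams with known
truth: a 42-receiver array with logistic distance detection (50% at 85 m),
V9/V13 tag duty cycles, within-day site/refuge tracks, and a
stratified-random zero-inflated survey. The per-fish-year residence table and
the year×zone relocation table from the source study ship as packaged
fixtures for exact arithmetic tests.

## Worked example

```python
from spawntrack import synth, telemetry, residence
from spawntrack.presence import SpawningPresenceModel, build_presence_records
from spawntrack.cpue import HurdleCPUEModel

truth = synth.TelemetryTruth()            # sex effect +1.0, peak ~1 July, semi-lunar
dep   = synth.default_deployments()
zmap  = telemetry.ZoneMap.from_deployments(dep, synth.default_zone_polygons())
tags  = synth.make_tags(seed=7)           # 31 fish: 20 V9 + 11 V13
sim   = synth.simulate_telemetry(truth, dep, tags, synth.default_control_tags(),
                                 ("2007-06-04", "2007-09-22"), seed=7)
kept, removed = telemetry.filter_spurious(sim.detections, dep)
post, study = telemetry.split_post_release(kept[kept.tag_id.isin(tags.tag_id)], tags)
pos   = telemetry.estimate_positions(study, dep, zone_map=zmap)
daily = residence.daily_presence(pos)
rec   = build_presence_records(daily, pos, tags)
fit   = SpawningPresenceModel(rec).fit()
print(fit.summary())
```

prints (seed 7):

```
Binomial additive mixed model (logit link)
  observations: 3027   log-likelihood: -1731.26   LAML: -1814.67
  random intercept SD (per fish): 0.709

Fixed effects:
  intercept    -0.4387  (SE 0.2331)
  sex[M]        1.1991  (SE 0.3204)
  size[F]       0.0049  (SE 0.0050)
  size[M]      -0.0012  (SE 0.0048)

Term tests (approximate Wald):
  sex        edf= 1.00  chi2=   14.01  p=0.000182
  size       edf= 2.00  chi2=    1.01  p=0.602
  s(doy)     edf= 2.83  chi2=   73.05  p=9.49e-16
  s(lunar)   edf= 5.63  chi2=  164.68  p=6.04e-33
```

The fitted male–female contrast (1.20 ± 0.32 logits) recovers the generating
value of +1.0; the seasonal smooth peaks in early July and the lunar smooth
is bimodal at the new and full moons, exactly the structure the generator
encodes. The spurious-detection filter removed 30 lone core-array detections
from 3.64 M simulated detections, and the whole-array and spawning-site
residence indices correlate at r = 0.97 across the 31 fish-years.

The survey arm runs the same way:

```python
survey = synth.simulate_survey(synth.default_survey_truth(), seed=7)
model  = HurdleCPUEModel.from_survey(survey.hauls, bandwidth=2.0, contour_level=0.5)
hfit   = model.fit()
index  = hfit.standardized_index(n_draws=10000, seed=7)
print(index.summary().loc[[1996, 2008, 2009, 2010, 2012]].round(2))
```

```
      mean  median  q2.5  q97.5
1996  1.87    1.86  1.44   2.37
2008  2.13    2.11  1.68   2.65
2009  1.18    1.16  0.89   1.52
2010  0.60    0.60  0.42   0.84
2012  1.01    1.00  0.76   1.30
```

The annual index (adults per haul, with 95% Monte-Carlo intervals) recovers
the generator's trajectory: stable through 2008, declining in 2009, lowest in
2010–2011. Forward AIC selected `year + month + region` for the presence
sub-model and `year + region + vegetation + season` for the positive-catch
sub-model on this replicate.

A command-line pipeline wraps the same functions:

```bash
spawntrack simulate --seed 7 --out-dir run/sim
spawntrack process-telemetry --detections run/sim/detections.csv \
    --deployments run/sim/deployments.csv --tags run/sim/tags.csv --out-dir run/tel
spawntrack residence --positions run/tel/positions.csv --tags run/sim/tags.csv \
    --out-dir run/res
spawntrack presence-model --positions run/tel/positions.csv --tags run/sim/tags.csv \
    --out-dir run/pm
spawntrack cpue --hauls run/sim/hauls.csv --out-dir run/cpue
spawntrack report --residence-dir run/res --out-dir run/rep
```

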