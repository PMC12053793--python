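# metapatch

Metapopulation analysis of species range limits from two-snapshot
plot-occupancy surveys.

A long-standing hypothesis holds that a geographic range limit can be
maintained not by niche or dispersal limitation alone but by gradients in
patch *colonisation* (c) and *extinction* (e): where colonisation of vacant
suitable habitat no longer keeps pace with extinction from occupied habitat,
patch occupancy dwindles and the metapopulation collapses. `metapatch`
implements the full analysis needed to test this with resurvey data from a
network of fixed plots censused in two years, and ships a stochastic
patch-occupancy simulator so every stage can be exercised against known
ground truth without any field data.

The pipeline, for plots indexed by along-coast distance *d* to the range
limit (0 at the limit, increasing toward the range core):

1. **Events.** Pair the two snapshots per plot. A plot vacant at the first
   survey and holding suitable habitat at the second is a *colonisation
   candidate* (colonised if occupied at the second survey); a plot occupied
   at the first survey is an *extinction candidate* regardless of later
   suitability. Local abundance L is the mean count over all other plots
   within 500 m.
2. **Models.** Binomial GLMs (logit link, IRLS, written from scratch in
   `metapatch.inference`) of colonisation and extinction on *d*; covariate
   models (suitable plot area, log10 local abundance, log10 initial
   abundance, with interactions) optionally extended with a per-plot
   Gaussian random effect with covariance sigma^2 exp(-h/rho) in inter-plot
   distance h, fitted by a Laplace-approximate marginal likelihood and
   compared by AICc; type II likelihood-ratio / Wald tests throughout.
3. **Equilibrium.** The Levins prediction

       n*(d) = c(d) / (c(d) + e(d)),

   the stationary occupancy of the per-plot two-state chain, evaluated from
   the fitted curves over a distance grid, with a pointwise percentile
   envelope from 1000 plot-level bootstrap refits, and compared with the
   95% confidence band of a binomial GLM of *observed* occupancy of
   suitable plots (containment fraction).
4. **Simulator** (`metapatch.spom`). A spatially explicit stochastic
   patch-occupancy model of ~3500 plots along a 938 km coastline: habitat
   areas declining toward the limit, habitat loss through succession, wind,
   driftwood and water (with cause bookkeeping), colonisation increasing in
   plot area and local abundance, extinction decreasing in initial abundance
   and area, and distance-declining abundances.

Estimators follow scikit-learn conventions (`GLM`, `SpatialGLMM` with
`fit`/`predict` and trailing-underscore attributes) and compose with
sklearn tooling; `ModelSpec`-driven helpers (`fit_glm`, `type2_tests`,
`predict_response`) cover the survey-analysis surface.

## Worked example

```sh
metapatch simulate --seed 7 --outdir demo
metapatch analyze demo/survey_2019.csv demo/survey_2022.csv \
    --seed 7 -B 1000 --no-spatial \
    --stages events,equilibrium,bootstrap,comparison --outdir demo_out
metapatch report demo_out/report.json
```

prints

```
plots paired: 3500
colonisation: 230/1315 (crude c = 0.175)
extinction:   251/823 (crude e = 0.305)
colonisation slope (log-odds per km toward core): +0.0007653
extinction slope (log-odds per km toward core): -0.0005187
n* containment in observed band: 1.000
  n_obs_core: 0.494
  n_obs_limit: 0.277
  n_star_core: 0.471
  n_star_limit: 0.261
```

Reading: 17.5% of the 1315 suitable-but-vacant plots were colonised over
the three-year interval and 30.5% of the 823 occupied plots went extinct.
Colonisation rises toward the range core (positive log-odds slope per km),
extinction falls slightly. Observed occupancy of suitable plots declines
from 0.494 at the core end of the survey to 0.277 at the range limit, and
the Levins prediction n* = c/(c+e) built only from the colonisation and
extinction models reproduces that decline (0.471 to 0.261), lying inside
the 95% band of the observed-occupancy model at every grid point
(containment 1.000) — the metapopulation signature of a dynamically
maintained range limit. `demo_out/` also contains the tidy per-plot event
table, the gridded curves and the full JSON report (add `--figures` for
PNG plots with the conventional reversed distance axis).

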