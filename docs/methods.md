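# Methods

## The model

Recruitment is the presence of at least one conifer seedling in a surveyed
plot. For plot *i* in wildfire *j*,

```
y_ij ~ Bernoulli(p_ij)
logit(p_ij) = x_ij' beta + log(area_ij [m^2]) + b_j,   b_j ~ N(0, sigma^2)
```

The log-area offset makes the linear predictor a per-square-meter rate, so
a prediction at 100 m^2 reads as "at least one seedling per 0.01 ha"
(100 stems/ha if exactly one). The random intercept absorbs everything
fires share (weather in the establishment years not captured by the
climate metrics, seed crops, survey crews). Fixed effects combine
biophysical predictors (time since fire, distance to seed source, RBR burn
severity, surrounding tree cover within 300 m, CHILI heat load, prefire
disturbance class, variety), optional quadratics, 30-y mean climatic water
deficit, postfire climate anomaly extremes, and selected interactions.
Continuous predictors are standardized before fitting (conditioning and
scale-free percentile machinery); raw-scale slopes are recovered by
back-transform.

## Estimation

The marginal likelihood integrates the fire intercepts out of the
Bernoulli likelihood. With a scalar intercept per fire it factorizes into
one-dimensional integrals, which we approximate by Laplace's method: an
inner damped Newton iteration finds each fire's conditional mode and
curvature, and the outer L-BFGS-B maximizes the approximate log-likelihood
over (beta, log sigma) (bounds on log sigma of [-10, 3]; the sigma -> 0
limit is evaluated exactly as the independent-Bernoulli likelihood).
Convergence requires projected-gradient norm below 1e-5 (1e-6 for final
fits), iteration cap 500. Wald covariances come from a central-difference
observed information of the Laplace objective in (beta, log sigma); the
beta block is reported.

An adaptive Gauss–Hermite evaluator of the same integrals (quadrature
centered at the conditional modes, scaled by the curvature) is the
numerical oracle: one node reproduces the Laplace value identically, and
the node count controls accuracy. The Laplace error per fire grows roughly
like sigma^4 for Bernoulli clusters: measured gaps against 50-node
quadrature are below 1e-2 for sigma <= 0.3 but reach ~0.07 around
sigma = 1 on 3–10-fire instances. This is a property of the approximation
(shared by standard mixed-model software in its Laplace mode), not an
implementation defect; the agreement test is therefore run in the
small-to-moderate dispersion regime, where the tolerance is informative
about correctness.

Two further estimation facts worth knowing:

- Duplicating every row leaves a plain (sigma = 0) logistic fit unchanged
  and shrinks its standard errors by exactly sqrt(2); in the mixed fit the
  equality is only approximate because the Laplace log-determinant term
  scales sublinearly and intercept information is limited by the number of
  fires, not plots.
- Simulation-based residuals (randomized quantiles against unconditional
  simulations with re-drawn fire intercepts) are close to marginally
  uniform even under covariate omission for binary data; misspecification
  shows up in residual-vs-covariate association, which is what the tests
  assert.

## Water balance

Monthly Thornthwaite PET (annual heat index from each calendar year's
monthly means; daylength correction from solar declination at mid-month;
PET = 0 for months at or below 0 degC) feeds Thornthwaite–Mather
bookkeeping: precipitation splits linearly into snow (fully snow <= 0 degC)
and rain (fully rain >= 6 degC); the snow store melts at 2 mm per degC-day
(configurable); when available water (rain + melt) is at least PET,
AET = PET and the surplus recharges the soil (capacity default 150 mm, a
typical forest soil) with the excess leaving as runoff; otherwise the soil
yields soil * (1 - exp(-(PET - W)/whc)) (exponential drying) and the
deficit is PET - AET. The first year is run once as spin-up and discarded.
Monthly mass balance closes to numerical precision and is asserted to
1e-6 mm.

Aggregation conventions (the original formulation leaves these open; all
are isolated in one function each): calendar-year annual deficit;
growing-season = April–September sums (precipitation summed, not
averaged); Jun–Aug VPD averaged; anomalies are z-scores against the
1981–2010 site baseline (sd with n-1; a zero-sd baseline yields z = 0 with
a warning); postfire extremes are the max and min of the annual z over
fire year + 1 .. + 5.

## Selection, thresholds

Model skill is the mean of per-fold AUCs from 10-fold cross-validation
whose folds partition fires — plot-level folds would leak the fire
intercept and inflate skill. Phase 1 repeatedly removes the climate term or
mean-climate x postfire-climate interaction whose removal gives the highest
CV AUC, while CV AUC improves; interactions must leave before their
parents; biophysical terms are protected. Phase 2 tests adding each
remaining postfire-climate x {RBR, distance, tree cover} interaction.
Ties break toward higher-order terms, then lexicographically; all
candidates within a round are compared on identical folds.

A caution established by simulation: under a pure-noise climate signal the
paired CV-AUC change from dropping one noise term is tiny
(~+1e-4) relative to its replicate noise (sd ~3e-3), so the greedy
stop-when-no-improvement rule stalls with spurious terms, or adds phase-2
interactions, in roughly half of replicates at 100 fires x 20 plots. Full
null recovery in >= 90% of runs is not statistically attainable for any
faithful greedy AUC rule at that size; the corresponding acceptance test
documents this and is expected to fail. Recovery of a true interaction
(effect -0.5 on standardized scales) is reliable (20/20 in our runs).

Probability cutoffs maximize Cohen's kappa or sensitivity + specificity
exactly: both objectives are step functions of the cutoff, so the midpoints
between adjacent sorted unique probabilities (plus 0 and 1) form a complete
candidate set; ties return the smallest cutoff; "likely" means probability
strictly above the cutoff. Cutoffs are chosen on out-of-fold probabilities
by default (in-sample optionally) to avoid optimism.

## Projection

Scenarios override the severity covariates with fixed bundles (low:
10 m / 30 % / RBR 100; high: 150 m / 10 % / RBR 400) at 10 y postfire and
100 m^2, with population-level prediction (fire intercept 0 — projections
target new fires). A 20-y period does not fix a fire year, so period-level
postfire anomaly inputs are the average of the 5-y-window extremes over all
fire years whose window fits in the series — the expectation for a fire
occurring in that period; 30-y means stay anchored to 1981–2010.
Classification is likely-both / likely-low-only / unlikely-both; a site
likely only under high severity contradicts the expected ordering and is
flagged anomalous but retained. Area summaries are area-weighted and sum
to 1 per region.

Partial dependence sweeps a focal covariate over its observed range
(100 points) with the others at medians (categoricals at the reference
level, "none" for disturbance; plot area at its median); with an
interacting covariate, curves are drawn at its 10th/50th/90th percentiles.
The 95% band is the 2.5/97.5 percentile envelope of curves from draws of
beta ~ N(beta-hat, Sigma-hat) (default 1,000). The band is parametric
uncertainty and does not narrow with more draws; what shrinks as
1/sqrt(draws) is the Monte-Carlo error of its endpoints, and that is what
the tests measure.

## Synthetic study

The generator emulates the structure of a pooled multi-fire survey: fires
uniform over 1984–2018 (capped at 2014 so the 5-y postfire window stays in
the historical record) with N(0, sigma^2) intercepts; one climate site per
fire (climate cells are coarse relative to fires); plots with log-uniform
areas 10–1,000 m^2 and uniform covariates over field-plausible ranges
(distance to seed source 0–500 m, tree cover 0–70 %, RBR 0–800, CHILI
0–255); five-level prefire disturbance dominated by "none"; survey delays
2–12 y. Monthly climate 1979–2050 has a sinusoidal seasonal cycle,
winter-wet gamma precipitation, temperature-driven VPD, interannual noise,
and an optional linear warming trend (default condition 0.35 degC/decade)
that propagates into a drying deficit trend. Default generating
coefficients give a presence rate near 0.28 with negative
distance/severity/deficit effects and a positive cover effect — imbalance
and signs typical of such surveys.

What it deliberately lacks: spatial autocorrelation, species identity and
range structure, serotiny, daily weather, and any real geography. Passing
tests therefore demonstrate that the estimation, selection, threshold and
projection machinery is correct and calibrated under the stated generating
process — not that the synthetic effect sizes match any real forest.

## Problem sizes and seeds

Test and acceptance problem sizes are chosen as the smallest that make the
statistical assertions sharp: 1,000 randomized 30-y series for closure;
20 small instances for quadrature agreement; 200 replicates of 100 fires x
20 plots for interval calibration; 20 replicates each for the selection
experiments; 100/30 random instances for the exact AUC/threshold oracles.
All randomness flows from explicit seeds (package default 20230306); the
pipeline derives per-stage seeds by hashing the stage name with the global
seed, so stage outputs are reproducible independently of execution order.
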