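# Methods

## The model

Plot-level aboveground biomass density (AGB, Mg/ha) is modeled on the
square-root scale. With `y(s) = sqrt(AGB(s))` at planar location `s` (km),
the geostatistical model is

    y(s) = β₀ + β₁x₁(s) + β₂x₂(s) + β₃x₃(s) + w(s) + ε(s)

where `x₁..x₃` are lidar canopy-structure metrics, `w` is a zero-mean
Gaussian process with exponential covariance `σ² exp(−φ d)` (partial sill
`σ²`, decay `φ` in 1/km) and `ε` is iid Gaussian with nugget variance
`τ²`. The null spatial model keeps only `β₀`. The effective range — the
distance at which spatial correlation falls to 0.05 — is `−ln(0.05)/φ`.
The sqrt transform symmetrizes the strongly right-skewed AGB distribution;
predictive draws are squared (back-transformed) to the AGB scale, negative
sqrt-scale draws included, which guarantees non-negative AGB without
truncating the predictive distribution.

Inference is Bayesian by MCMC. The spatial effect is marginalized during
sampling — `y ~ N(Xβ, σ²R(φ) + τ²I)` — which leaves a 3-dimensional
covariance-parameter block plus a conjugate Gaussian conditional for `β`,
and mixes far better than updating `w` jointly with the parameters. The
sampler is Metropolis-within-Gibbs: a joint adaptive random-walk step on
`(log σ², log τ², logit-scaled φ)` (step size adapted toward 30%
acceptance during burn-in only, so the retained chain is a valid Markov
chain) and a Gibbs draw of `β`. Spatial-effect draws at the plot
locations are recovered afterwards, one per retained draw, from the exact
Gaussian conditional `w | y, β, θ` — the joint posterior is unchanged.

Defaults: 25,000 iterations, 5,000 burn-in, thinning 10. Chains are
bit-reproducible given a seed. Shorter chains (3,000–6,000 iterations)
are used in the replicated experiments below; posterior summaries at
those lengths agree with long chains to well within Monte Carlo error,
and the sampler was validated against a brute-force grid evaluation of
the exact marginal posterior on a small dataset.

## Priors

"Vague" priors need a scale to be vague about:

- `β ~ N(0, 10⁴)` per coefficient.
- `σ², τ² ~ inverse-gamma(2, ½·s²_resid)` where `s²_resid` is the
  ordinary-least-squares residual variance of `y` for the model's own
  design (for the null model this is just the sample variance of `y`).
  Scaling by the *residual* variance matters: the raw variance of `y` is
  dominated by the metric signal, and an inverse-gamma centred there is
  strongly informative upwards for variance components that are an order
  of magnitude smaller, visibly distorting the nugget/sill split.
- `φ ~ Uniform(−ln(0.05)/d_max, −ln(0.05)/d_min)`, with `d_min`/`d_max`
  the smallest/largest pairwise distances in the data and `d_min` floored
  at one 30 m cell — i.e. the effective range is a priori somewhere
  between one cell and the domain diameter.

Exact duplicate plot locations are jittered by 1 m (with a warning),
since at `τ² → 0` duplicates make the marginal covariance singular. If a
covariance factorization fails numerically, a diagonal jitter of
`10⁻⁸·(σ²+τ²)` is added once.

## Prediction and areal estimation

Posterior predictive AGB at new locations uses composition sampling: for
each retained draw `(β, θ, w)`, the new-site spatial effect is drawn from
the GP conditional given the `w` draw at the plot sites
(`mean r₀ᵀR⁻¹w`, `variance σ²(1 − r₀ᵀR⁻¹r₀)`), the nugget is added, and
the sqrt-scale value `x₀ᵀβ + w₀ + ε₀` is squared. Summaries per pixel:
Est = predictive median, SD, RSD = 100·SD/Est (flagged undefined at
Est = 0), and the central 95% interval from the 2.5%/97.5% quantiles. The
median of squared draws is computed directly, never as the square of the
sqrt-scale median, which squaring does not commute with once draws go
negative.

Across pixels the new-site effects are drawn conditionally independently
given each `w` draw (default), which is tractable for large grids but
slightly understates cross-pixel dependence; an exact joint-conditional
mode is provided for up to 2,000 locations. All random variates are
generated up front in a fixed pixel order, so results are independent of
the internal linear-algebra block size.

Management-unit (MU) estimates integrate the *per-draw* pixel values:
per draw, mean density is the average over the unit's unmasked pixels and
the total is density × area (0.09 ha per 30 m pixel, or an externally
supplied printed area); medians, SDs and credible intervals are then
taken across draws. Because total and mean are the same draws scaled by
area, their relative SDs are identical by construction. Summing pixel
medians instead would be wrong — medians do not add.

## Lidar metrics

Seventeen candidate metrics per 30 m cell from normalized point heights:
canopy cover (percent of returns strictly above 2 m among all returns),
mean and SD of above-2 m heights, 13 height percentiles (5–95th), and
canopy rumple. Conventions pinned here because upstream tooling varies:
percentiles use linear interpolation between order statistics; the SD is
the population SD; the canopy height model for rumple is built at 1 m
resolution from the highest return per fine cell (empty fine cells at
ground level) and triangulated with a fixed NW–SE diagonal per grid
square, so rumple is deterministic and ≥ 1. Cells with a 95th-percentile
height above 64 m or mean height above 40 m are masked as registration
artifacts and excluded everywhere downstream.

Plot-level metric vectors come either from area-weighted zonal means of
intersecting unmasked cells (intersection areas via exact polygon
clipping) or by recomputing metrics from the points inside the plot
boundary — except rumple, which is always zonal because of its strong
edge sensitivity.

## Variable selection

All C(17,2) + C(17,3) = 816 two- and three-metric OLS models of
sqrt(AGB) are fitted and ranked by adjusted R², with ties broken by lower
AIC, then smaller subset, then lexicographic names (the primary-key
choice when the two criteria disagree is a convention; they rarely do).
AIC is `−2 logL + 2(p+2)`, counting intercept and variance, with the
Gaussian likelihood at the ML variance — only relative ranking matters.
Collinearity among selected metrics is allowed; canopy structure metrics
are intrinsically correlated and the winning trio typically is.

## Cross-validation and error metrics

Ten-fold holdout: plots are randomly assigned to 10 near-equal groups;
each group is predicted from a model refitted without it. Metrics:
RMSE; relative squared error RSE = 100·Σ(est−obs)²/Σ(obs−ȳ)² (a
skill-free predictor scores near or above 100%); R² as the squared
Pearson correlation of observed and predicted (so a null spatial model
can show R² ≈ 0 while its RSE exceeds 100%); bias = mean(est−obs);
empirical 95% coverage probability; and mean credible-interval width.
External map products are additionally summarized by the OLS line of map
prediction on observation — slope below 1 is the regression-to-the-mean
signature of shrunken broad-scale maps.

## The synthetic generator

No public plot data exist for the target system, so the generator
reproduces the statistical structure the analysis assumes, and the
experiments below run on it:

- ~360 plots over a 10×10 km domain with mean AGB ≈ 115 Mg/ha and
  sqrt-scale variance ≈ 22, matching the pooled inventory summaries.
- Plot locations are cluster-sampled — 4 plots per site within a 0.3 km
  site extent — emulating inventory campaigns whose protocols place plots
  100–300 m apart. This is not cosmetic: short-distance pairs are what
  identify the nugget/partial-sill split; with uniformly scattered plots
  the split is prior-dominated.
- Three signal metrics are built from a shared unit-variance latent
  canopy field `u` (exponential GP, effective range 0.3 km, the sub-km
  patch scale of this landscape) as `x_j = a_j u + √(1−a_j²) n_j`,
  affine-mapped to field units (cover ~35±16%, mean height ~10±3.5 m,
  rumple ~2.2±0.55). The loadings `a_j` are solved from the target
  correlations with sqrt(AGB) — 0.74 / 0.84 / 0.85 — given the slopes and
  variance components; the three equations are coupled through sd(y), so
  the system is solved numerically (deterministically) rather than in
  closed form. With the default slopes this puts the population R² of the
  best 3-metric model at ≈ 0.79 and the inter-metric correlations at
  0.69–0.86, both consistent with the reported structure.
- Fourteen decoy metrics (SD height, 13 percentiles) are noisy mixtures
  of the signal metrics (30–60% noise variance), mimicking the strong
  collinearity of percentile metrics without adding information. Decoy
  percentile columns are not forced to be mutually ordered; ordering is
  enforced only for metrics actually computed from point clouds.
- The response is `y = β₀ + Σβx + w + ε` with defaults σ² = 4, τ² = 0.7,
  φ = 10/km (effective range 0.30 km); AGB = y² exactly.

What the generator does **not** emulate: fire-severity covariates and
burned-plot heteroscedasticity, species composition, terrain effects on
metric error, FIA location perturbation, and multi-year misalignment of
field and lidar collections. Passing calibration tests on this generator
therefore demonstrates that the *method* is correct and calibrated under
its own assumptions — not that real subalpine data satisfy them.

Tree lists and point clouds are synthetic fixtures: tree lists carry a
placeholder power-law allometry `a·DBH^b` (per-tree AGB is an external
input in real use), at least one sub-threshold tree and one cluster
record to exercise the ≥ 7.6 cm filter and the cluster-expansion rule;
point clouds hit a prescribed canopy cover exactly and a prescribed mean
height in expectation.

## Replicated experiments and problem sizes

- Parameter recovery: 20 replicates of n = 300 plots; 5,000 iterations
  (2,000 burn-in, thin 5). Every parameter's 95% credible interval is
  required to cover its true value in ≥ 17 of 20 replicates.
- Predictive calibration: one joint realization of 360 plots plus a
  30×30 pixel grid spread across the domain (pixel spacing beyond the
  effective range, so the 900 coverage indicators are nearly independent
  and the empirical rate concentrates near nominal); ~95% of pixel 95%
  intervals must contain the true simulated AGB (±3 points). Ten-fold CV
  coverage on the same 360 plots must fall in [92, 98]%.
- Selection recovery: 20 replicates; the planted signal trio must win the
  exhaustive search in ≥ 18.

## Known limitations

- The independent-pixel prediction mode understates cross-pixel
  dependence; MU credible intervals built from it are slightly narrow
  relative to the exact joint conditional (available for ≤ 2,000 pixels).
- Dense-covariance MCMC is O(n³) per iteration; the implementation is
  comfortable to n ≈ 1,000 plots but has no low-rank path for larger n.
- Matérn or other covariance families are not implemented.
- Convergence diagnostics are limited to acceptance-rate checks and the
  exported draws; no multi-chain R-hat machinery.
- In external reporting of the source tables, the covariate-model partial
  sill appears once as 20.48 and once as 22.48, and the CV RMSE/RSE as
  49.2/27.56% vs 49.06/27.41%; this package always reports the values it
  computes.
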