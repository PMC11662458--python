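# lidar-agb

Bayesian geostatistical estimation of forest aboveground biomass (AGB)
from airborne-lidar canopy-structure metrics, with honest uncertainty at
every scale: 30 m pixels, whole management units, and held-out plots.

Broad-scale optical-imagery biomass maps are calibrated mostly on
lower-elevation forests and degrade in heterogeneous, undersampled
systems such as Sierra Nevada subalpine forest. This package implements
the local alternative: fit a spatial model to a few hundred field plots
with collocated lidar, and propagate the full posterior into maps and
regional totals. It is aimed at forest-carbon analysts and spatial
statisticians who need credible intervals they can defend, not just a
prediction surface.

## The model

With `y(s) = √AGB(s)` (Mg/ha, square-root scale) at planar location `s`:

```
y(s) = β₀ + β₁x₁(s) + β₂x₂(s) + β₃x₃(s) + w(s) + ε(s)
```

- `x₁..x₃` — lidar metrics chosen by exhaustive 2-/3-variable OLS search
  over 17 candidates (canopy cover, mean/SD height, 13 height
  percentiles, canopy rumple), ranked by adjusted R²/AIC;
- `w(s)` — zero-mean Gaussian process, exponential covariance
  `σ² exp(−φd)` (effective range `−ln 0.05/φ`);
- `ε(s)` — iid nugget, variance `τ²`; the null spatial model keeps only β₀.

Fitting is by MCMC with `w` marginalized (adaptive Metropolis-within-
Gibbs); prediction is by composition sampling of the posterior
predictive distribution (PPD), squared back to the AGB scale; pixels are
summarized by the PPD median (Est), SD, RSD = 100·SD/Est and central 95%
interval; management-unit totals integrate per-draw pixel values so the
unit's credible interval is exact with respect to the sampled posterior.
Validation is ten-fold cross-validation reporting RMSE, relative squared
error, R², bias, empirical 95% coverage and interval width.

Because the source field data are not public, the package ships a
first-class synthetic generator that reproduces the system's statistical
structure (~360 clustered plots, strong spatial dependence with small
nugget-to-sill, three signal metrics correlated 0.74/0.84/0.85 with
√AGB plus 14 collinear decoys). See `docs/methods.md` for every
convention and its rationale.

## Worked example

```python
import numpy as np
from lidar_agb import (BiomassGeostatModel, SimulationConfig, METRIC_NAMES,
                       generate_scene, select_best, summarize_pixels,
                       mu_joint_estimate)

# synthetic study area: 360 plots + a 30x30 pixel grid, one realization
dataset, grid = generate_scene(SimulationConfig(seed=7), grid_shape=(30, 30))

sel = select_best(dataset.plots["agb_sqrt"], dataset.metrics,
                  metric_names=list(METRIC_NAMES))
print("best subset:", sel.best.metric_subset,
      f"adjusted R2 = {sel.best.adjusted_r2:.2f}")

model = BiomassGeostatModel.from_dataframe(
    dataset.plots, dataset.metrics, metric_names=sel.best_subset())
result = model.fit(n_iter=6000, n_burn=2000, thin=5, seed=1)
print(result.summary_text())

pred = result.predict(grid.table[["x_km", "y_km"]].to_numpy(),
                      grid.table, seed=2)
pixels = summarize_pixels(pred.agb_draws)
mu = mu_joint_estimate(pred.agb_draws, grid.table["mu_id"],
                       pixel_area_ha=(grid.cell_size_m / 100.0) ** 2)
```

Output:

```
best subset: ('canopy_cover_pct', 'canopy_rumple', 'mean_height_m') adjusted R2 = 0.82
Biomass geostatistical model (covariate), n=360, draws=800, acceptance=0.29
            beta_0    -4.801 (-5.746, -3.854)
  beta_canopy_cover_pct     0.076 (0.058, 0.096)
  beta_canopy_rumple     3.778 (3.011, 4.566)
  beta_mean_height_m     0.335 (0.222, 0.442)
              tau2     0.759 (0.325, 1.824)
            sigma2     3.214 (2.014, 4.046)
               phi    13.149 (8.535, 20.213)
      eff_range_km     0.228 (0.148, 0.351)
```

The exhaustive search recovers the three structure metrics that actually
drive biomass; each coefficient row is the posterior median with its 95%
credible interval. The partial sill σ² dominates the nugget τ²
(spatially structured residual variation with an effective range of
roughly 230 m), exactly the regime where a spatial random effect earns
its keep. The first pixels of the map summary:

```
     est    sd  rsd_pct  ci_lo  ci_hi
0   80.8  35.8     44.3   26.5  161.7
1   39.0  19.7     50.4    8.9   82.9
2  151.6  48.3     31.8   69.4  262.8
```

Single 30 m pixels are individually uncertain (RSD 30–50%), but
averaging tames the spread: the two 5,000 ha management units come out
at 117.0 and 112.2 Mg/ha mean density (totals 0.585 / 0.561 Tg) with an
RSD under 3% — the central claim of unit-level carbon accounting from a
jointly sampled posterior.

The same workflow is scriptable end to end (`simulate → select → fit →
predict → aggregate → validate`) through the CLI:

```sh
lidar-agb run config.yaml --workdir out/
```

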