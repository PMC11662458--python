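"""Synthetic plot, grid, tree-list and point-cloud generators.

The generators emulate the statistical structure the analysis assumes: a
few hundred field plots scattered over a ~10x10 km subalpine domain whose
sqrt-scale AGB carries strong spatial dependence (small nugget-to-sill),
and a 17-column candidate metric table in which three "signal" metrics
(canopy cover, mean height, canopy rumple) correlate with sqrt(AGB) at
roughly 0.74 / 0.84 / 0.85 while the remaining 14 columns are noisy
mixtures of the signal metrics (stand-ins for height percentiles and the
like, which in real acquisitions are highly collinear with the signal
trio).

Construction: a unit-variance latent canopy field u (spatially structured)
drives each standardized signal metric s_j = a_j u + sqrt(1-a_j^2) n_j; the
response is y = x' beta + w + eps with w a Gaussian process (partial sill
sigma2, decay phi) and iid nugget eps.  The loadings a_j are solved from
the target correlations given beta and the variance components, so the
generated correlations match the targets in population.  Negative sqrt-
scale responses are kept and squared (consistent with the back-transform
used throughout); AGB = y^2 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform
from scipy.stats import truncnorm

__all__ = [
    "METRIC_NAMES", "SIGNAL_METRICS", "SimulationConfig", "SyntheticDataset",
    "PixelGrid", "simulate_gaussian_random_field", "generate_plot_dataset",
    "generate_pixel_grid", "generate_scene", "generate_tree_list",
    "generate_point_cloud",
]

SIGNAL_METRICS = ("canopy_cover_pct", "mean_height_m", "canopy_rumple")
_PCTS = (5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95)
DECOY_METRICS = ("sd_height_m",) + tuple(f"p{q:02d}" for q in _PCTS)
#: the 17 candidate structure metrics, signal trio first.
METRIC_NAMES = SIGNAL_METRICS + DECOY_METRICS

# affine maps from standardized metrics to field-realistic units
_SIGNAL_LOC = np.array([35.0, 10.0, 2.2])
_SIGNAL_SCALE = np.array([16.0, 3.5, 0.55])
# default standardized slopes; on the physical scale beta_j = b_std_j / scale_j
_BETA_STD_DEFAULT = np.array([1.0, 1.7, 1.8])
_MEAN_SQRT_AGB = 9.6


def _default_beta() -> tuple[float, ...]:
    slopes = _BETA_STD_DEFAULT / _SIGNAL_SCALE
    b0 = _MEAN_SQRT_AGB - float(slopes @ _SIGNAL_LOC)
    return (b0, *slopes)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative truth for the synthetic plot/grid datasets.

    beta is on the physical metric scale: intercept plus one slope per
    signal metric, in sqrt(Mg/ha) per metric unit.  sigma2/tau2/phi are the
    sqrt-scale partial sill, nugget, and spatial decay (1/km).
    target_correlations are the desired correlations of the three signal
    metrics with sqrt(AGB); set to None for a fully deterministic generator
    (no metric noise, loadings fixed at 1) used in degenerate-case tests.
    """

    n_plots: int = 360
    domain_km: tuple[float, float] = (10.0, 10.0)
    beta: tuple[float, ...] = field(default_factory=_default_beta)
    sigma2: float = 4.0
    tau2: float = 0.7
    phi: float = 10.0
    latent_sigma2: float = 1.0
    latent_phi: float = 10.0
    plots_per_site: int = 4
    site_extent_km: float = 0.3
    n_decoy_metrics: int = 14
    target_correlations: tuple[float, float, float] | None = (0.74, 0.84, 0.85)
    plot_area_ha: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if self.sigma2 < 0 or self.tau2 < 0 or self.latent_sigma2 < 0:
            raise ValueError("variance components must be >= 0")
        if self.phi <= 0 or self.latent_phi <= 0:
            raise ValueError("spatial decay parameters must be > 0")
        if len(self.beta) != len(SIGNAL_METRICS) + 1:
            raise ValueError("beta must be intercept + one slope per signal metric")
        if self.target_correlations is not None:
            r = np.asarray(self.target_correlations, dtype=float)
            if r.size != len(SIGNAL_METRICS) or np.any(np.abs(r) >= 1):
                raise ValueError("target correlations must lie in (-1, 1), one "
                                 "per signal metric")

    @property
    def beta_std(self) -> np.ndarray:
        """Slopes on the standardized-metric scale."""
        return np.asarray(self.beta[1:], dtype=float) * _SIGNAL_SCALE


@dataclass
class SyntheticDataset:
    """Plots plus candidate metrics with full generative truth attached."""

    plots: pd.DataFrame
    metrics: pd.DataFrame
    truth: SimulationConfig
    true_w: np.ndarray
    loadings: np.ndarray  # a_j solved from the target correlations


@dataclass
class PixelGrid:
    """Regular pixel grid sharing the plot-level generative process.

    table columns: row, col, x_km, y_km, the 17 metrics, true_w,
    true_agb_mg_ha, mu_id (management-unit label).
    """

    table: pd.DataFrame
    cell_size_m: float
    shape: tuple[int, int]


def simulate_gaussian_random_field(locations_km, sigma2: float, phi: float,
                                   seed=0) -> np.ndarray:
    """One draw of a zero-mean Gaussian process with covariance
    sigma2*exp(-phi*d) at the given locations (km).

    Coincident locations receive identical values: the draw is made on the
    unique locations and broadcast back, which also keeps the covariance
    factorable.  Factorization falls back to a 1e-8-scaled diagonal jitter.
    """
    locs = np.atleast_2d(np.asarray(locations_km, dtype=float))
    if not np.all(np.isfinite(locs)):
        raise ValueError("non-finite coordinates")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sigma2 == 0:
        return np.zeros(locs.shape[0])
    uniq, inverse = np.unique(locs, axis=0, return_inverse=True)
    C = sigma2 * np.exp(-phi * squareform(pdist(uniq)))
    from .model import _chol_with_jitter
    L = _chol_with_jitter(C, sigma2)[0]
    vals = L @ rng.standard_normal(uniq.shape[0])
    return vals[np.asarray(inverse).ravel()]


def _solve_loadings(config: SimulationConfig) -> np.ndarray:
    """Solve the signal loadings a_j so that corr(x_j, y) hits the targets.

    With standardized x_j = a_j u + sqrt(1-a_j^2) n_j the correlations are
        r_j = (a_j S + b_j (1 - a_j^2)) / sd(y),  S = sum_k b_k a_k,
        var(y) = S^2 + sum_k b_k^2 (1 - a_k^2) + sigma2 + tau2,
    a coupled 3x3 system solved numerically (deterministic).
    """
    if config.target_correlations is None:
        return np.ones(len(SIGNAL_METRICS))
    r = np.asarray(config.target_correlations, dtype=float)
    b = config.beta_std
    s2n = config.sigma2 + config.tau2

    def resid(a):
        S = float(b @ a)
        V = S ** 2 + float(b ** 2 @ (1 - a ** 2)) + s2n
        return (a * S + b * (1 - a ** 2)) / np.sqrt(V) - r

    sol = least_squares(resid, x0=np.full(r.size, 0.6),
                        bounds=(1e-9, 1 - 1e-9), xtol=1e-14, ftol=1e-14)
    if np.max(np.abs(sol.fun)) > 1e-6:
        raise ValueError(
            "target correlations are unachievable for the given beta and "
            f"variance components (residual {np.max(np.abs(sol.fun)):.3g})")
    return sol.x


def _decoy_params(config: SimulationConfig, rng: np.random.Generator):
    """Per-decoy mixing weights over the signal metrics and noise fractions."""
    k = config.n_decoy_metrics
    weights = rng.dirichlet(np.ones(len(SIGNAL_METRICS)), size=k)
    noise_frac = rng.uniform(0.3, 0.6, size=k)
    return weights, noise_frac


def _decoy_units(k: int):
    """Affine maps giving the decoy columns plausible field units."""
    names = list(DECOY_METRICS[:k])
    loc, scale = [], []
    for nm in names:
        if nm == "sd_height_m":
            loc.append(4.0)
            scale.append(1.2)
        else:
            q = int(nm[1:])
            loc.append(3.0 + 0.12 * q)
            scale.append(2.5)
    return names, np.array(loc), np.array(scale)


def _build_metrics_and_response(u, w, config, a, decoys, rng):
    """Metrics table and sqrt-scale response at locations with fields u, w."""
    n = u.size
    deterministic = config.target_correlations is None
    b_phys = np.asarray(config.beta[1:], dtype=float)

    if deterministic:
        s = np.tile(u[:, None], (1, len(SIGNAL_METRICS)))
    else:
        noise = rng.standard_normal((n, len(SIGNAL_METRICS)))
        s = a[None, :] * u[:, None] + np.sqrt(1 - a ** 2)[None, :] * noise

    X = _SIGNAL_LOC[None, :] + _SIGNAL_SCALE[None, :] * s
    # keep physically meaningful ranges; the clip probability is ~1% at the
    # default scales so the correlation targets move by well under 0.01
    X[:, 0] = np.clip(X[:, 0], 0.0, 100.0)
    X[:, 2] = np.maximum(X[:, 2], 1.0)

    weights, noise_frac = decoys
    k = weights.shape[0]
    names, dloc, dscale = _decoy_units(k)
    S_s = np.outer(a, a)
    np.fill_diagonal(S_s, 1.0)
    D = np.empty((n, k))
    for j in range(k):
        c = weights[j]
        base = s @ c
        var = float(c @ S_s @ c)
        base = base / np.sqrt(max(var, 1e-12))
        if deterministic:
            D[:, j] = base
        else:
            D[:, j] = (np.sqrt(1 - noise_frac[j]) * base
                       + np.sqrt(noise_frac[j]) * rng.standard_normal(n))
    D = dloc[None, :] + dscale[None, :] * D

    eps = (np.zeros(n) if config.tau2 == 0
           else rng.normal(0.0, np.sqrt(config.tau2), size=n))
    y = config.beta[0] + X @ b_phys + w + eps
    metrics = pd.DataFrame(np.column_stack([X, D]),
                           columns=list(SIGNAL_METRICS) + names)
    return metrics, y


def generate_plot_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a plot table plus 17-column metric table from the config.

    Deterministic given config.seed; regenerating reproduces every value
    bit-for-bit.  The AGB column is exactly the square of the sqrt-scale
    response (negative responses squared as-is, no truncation).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    a = _solve_loadings(config)
    locs = _plot_locations(config, rng)
    u = simulate_gaussian_random_field(locs, config.latent_sigma2,
                                       config.latent_phi, rng)
    w = simulate_gaussian_random_field(locs, config.sigma2, config.phi, rng)
    decoys = _decoy_params(config, rng)
    metrics, y = _build_metrics_and_response(u, w, config, a, decoys, rng)

    plots = pd.DataFrame({
        "plot_id": [f"P{i:04d}" for i in range(config.n_plots)],
        "x_km": locs[:, 0],
        "y_km": locs[:, 1],
        "area_ha": config.plot_area_ha,
        "agb_mg_ha": y ** 2,
        "agb_sqrt": y,
        "dataset_tag": "synthetic",
        "year": 2020,
    })
    metrics.insert(0, "plot_id", plots["plot_id"])
    return SyntheticDataset(plots=plots, metrics=metrics, truth=config,
                            true_w=w, loadings=a)


def _plot_locations(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Cluster-sampled plot locations emulating inventory campaigns.

    Field plots are installed in local sites (monitoring grids, fire
    transects) with members a few hundred meters apart, and it is those
    short-distance pairs that identify the nugget/partial-sill split.
    Sites are uniform over the domain; plots scatter uniformly within a
    site_extent_km box around each site center (clipped to the domain).
    """
    lx, ly = config.domain_km
    k = max(int(config.plots_per_site), 1)
    n = config.n_plots
    n_sites = int(np.ceil(n / k))
    centers = np.column_stack([rng.uniform(0, lx, n_sites),
                               rng.uniform(0, ly, n_sites)])
    locs = (np.repeat(centers, k, axis=0)[:n]
            + rng.uniform(-config.site_extent_km / 2,
                          config.site_extent_km / 2, size=(n, 2)))
    return np.clip(locs, [0, 0], [lx, ly])


def _grid_centers(extent_km, cell_size_km):
    (x0, x1), (y0, y1) = extent_km
    nx = int(np.floor((x1 - x0) / cell_size_km + 1e-9))
    ny = int(np.floor((y1 - y0) / cell_size_km + 1e-9))
    if nx < 2 or ny < 2:
        raise ValueError("extent must span at least 2x2 cells")
    xs = x0 + cell_size_km * (np.arange(nx) + 0.5)
    ys = y0 + cell_size_km * (np.arange(ny) + 0.5)
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    cx, cy = np.meshgrid(xs, ys)
    return rows.ravel(), cols.ravel(), cx.ravel(), cy.ravel(), (ny, nx)


def generate_pixel_grid(config: SimulationConfig | None = None,
                        extent_km=None, cell_size_m: float = 30.0) -> PixelGrid:
    """Pixel grid of metrics plus true AGB sharing the plot-level process.

    Cells are labeled with two management units (west/east halves).  The
    grid draws its own latent and spatial fields; use generate_scene for a
    grid drawn jointly with a plot dataset.
    """
    config = config or SimulationConfig()
    if cell_size_m <= 0:
        raise ValueError("cell size must be > 0")
    if extent_km is None:
        extent_km = ((0.0, config.domain_km[0]), (0.0, config.domain_km[1]))
    rng = np.random.default_rng(config.seed)
    rows, cols, cx, cy, shape = _grid_centers(extent_km, cell_size_m / 1000.0)
    locs = np.column_stack([cx, cy])
    a = _solve_loadings(config)
    u = simulate_gaussian_random_field(locs, config.latent_sigma2,
                                       config.latent_phi, rng)
    w = simulate_gaussian_random_field(locs, config.sigma2, config.phi, rng)
    decoys = _decoy_params(config, rng)
    metrics, y = _build_metrics_and_response(u, w, config, a, decoys, rng)
    table = pd.DataFrame({"row": rows, "col": cols, "x_km": cx, "y_km": cy})
    table = pd.concat([table, metrics.reset_index(drop=True)], axis=1)
    table["true_w"] = w
    table["true_agb_mg_ha"] = y ** 2
    table["mu_id"] = np.where(cx <= np.median(cx), 1, 2)
    return PixelGrid(table=table, cell_size_m=cell_size_m, shape=shape)


def generate_scene(config: SimulationConfig | None = None,
                   grid_shape: tuple[int, int] = (30, 30),
                   grid_extent_km=None):
    """Jointly simulate a plot dataset and a pixel grid on one realization.

    The latent canopy field and the spatial effect are drawn once over the
    union of plot and pixel locations, so a model fitted to the plots sees
    the same surfaces that generated the grid's true AGB — the setting for
    predictive-calibration checks.  Returns (SyntheticDataset, PixelGrid).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    a = _solve_loadings(config)
    lx, ly = config.domain_km
    plot_locs = _plot_locations(config, rng)
    if grid_extent_km is None:
        grid_extent_km = ((0.0, lx), (0.0, ly))
    ny, nx = grid_shape
    cell_km = min((grid_extent_km[0][1] - grid_extent_km[0][0]) / nx,
                  (grid_extent_km[1][1] - grid_extent_km[1][0]) / ny)
    rows, cols, cx, cy, shape = _grid_centers(grid_extent_km, cell_km)
    grid_locs = np.column_stack([cx, cy])

    all_locs = np.vstack([plot_locs, grid_locs])
    u = simulate_gaussian_random_field(all_locs, config.latent_sigma2,
                                       config.latent_phi, rng)
    w = simulate_gaussian_random_field(all_locs, config.sigma2, config.phi, rng)
    decoys = _decoy_params(config, rng)
    metrics, y = _build_metrics_and_response(u, w, config, a, decoys, rng)

    n = config.n_plots
    plots = pd.DataFrame({
        "plot_id": [f"P{i:04d}" for i in range(n)],
        "x_km": plot_locs[:, 0],
        "y_km": plot_locs[:, 1],
        "area_ha": config.plot_area_ha,
        "agb_mg_ha": y[:n] ** 2,
        "agb_sqrt": y[:n],
        "dataset_tag": "synthetic",
        "year": 2020,
    })
    pmetrics = metrics.iloc[:n].reset_index(drop=True).copy()
    pmetrics.insert(0, "plot_id", plots["plot_id"])
    dataset = SyntheticDataset(plots=plots, metrics=pmetrics, truth=config,
                               true_w=w[:n], loadings=a)

    gtable = pd.DataFrame({"row": rows, "col": cols, "x_km": cx, "y_km": cy})
    gtable = pd.concat([gtable, metrics.iloc[n:].reset_index(drop=True)], axis=1)
    gtable["true_w"] = w[n:]
    gtable["true_agb_mg_ha"] = y[n:] ** 2
    gtable["mu_id"] = np.where(cx <= np.median(cx), 1, 2)
    grid = PixelGrid(table=gtable, cell_size_m=cell_km * 1000.0, shape=shape)
    return dataset, grid


def generate_tree_list(target_agb_mg_ha: float, plot_area_ha: float,
                       allometry: tuple[float, float] = (0.05, 2.5),
                       seed: int = 0) -> pd.DataFrame:
    """Tree list whose qualifying AGB density hits the target within 0.5%.

    Trees carry placeholder power-law AGB (a * dbh^b).  The list always
    includes at least one sub-threshold tree (DBH < 7.6 cm) and one cluster
    record (cluster_count > 1) so downstream filters and the expansion rule
    are exercised.  The last qualifying tree's DBH is solved from the
    allometry so the density round-trip is exact up to floating point.
    """
    if target_agb_mg_ha < 0:
        raise ValueError("target AGB must be >= 0")
    if plot_area_ha <= 0:
        raise ValueError("plot area must be > 0")
    a_coef, b_coef = allometry
    if a_coef <= 0 or b_coef <= 0:
        raise ValueError("allometry coefficients must be positive")
    rng = np.random.default_rng(seed)

    def agb(dbh):
        return a_coef * dbh ** b_coef

    rows = []
    # one sub-threshold single tree and one sub-threshold cluster
    rows.append(("PIAL", 5.0, 3.5, "live", agb(5.0), 1))
    rows.append(("PIAL", 6.0, 4.0, "live", agb(6.0), 2))

    target_kg = target_agb_mg_ha * plot_area_ha * 1000.0
    cum = 0.0
    first = True
    while cum < target_kg and target_kg > 0:
        dbh = float(np.clip(rng.lognormal(np.log(20.0), 0.4), 7.6, 120.0))
        count = 2 if first else 1
        contrib = count * agb(dbh)
        if cum + contrib > target_kg and not first:
            break
        status = "dead" if rng.uniform() < 0.2 else "live"
        height = 1.37 + 0.8 * dbh ** 0.85
        rows.append(("PIAL", dbh, height, status, agb(dbh), count))
        cum += contrib
        first = False
    remaining = target_kg - cum
    if remaining > 1e-12:
        dbh_f = (remaining / a_coef) ** (1.0 / b_coef)
        if dbh_f >= 7.6:
            rows.append(("PIAL", dbh_f, 1.37 + 0.8 * dbh_f ** 0.85, "live",
                         agb(dbh_f), 1))
        else:
            # fold the remainder into the previous singleton tree
            sp, dbh, h, st, kg, cnt = rows[-1]
            new_kg = kg + remaining / cnt
            new_dbh = (new_kg / a_coef) ** (1.0 / b_coef)
            rows[-1] = (sp, new_dbh, h, st, new_kg, cnt)
    return pd.DataFrame(rows, columns=["species", "dbh_cm", "height_m",
                                       "status", "agb_kg", "cluster_count"])


def generate_point_cloud(target_cover_pct: float,
                         target_mean_height_m: float | None = None,
                         n_points: int = 1000, cell_size_m: float = 30.0,
                         height_sd_m: float | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Normalized-height point cloud with a prescribed canopy cover.

    Exactly round(n * cover/100) points lie above the 2 m canopy threshold;
    their heights are drawn around the target mean (exactly equal to it
    when height_sd_m=0).  Columns: x, y, z (meters, z normalized height).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not (0 <= target_cover_pct <= 100):
        raise ValueError("cover must be in [0, 100]")
    if target_cover_pct > 0:
        if target_mean_height_m is None or target_mean_height_m <= 2.0:
            raise ValueError("mean height must exceed 2 m when cover > 0")
    rng = np.random.default_rng(seed)
    n_above = int(round(n_points * target_cover_pct / 100.0))
    n_below = n_points - n_above
    x = rng.uniform(0, cell_size_m, n_points)
    y = rng.uniform(0, cell_size_m, n_points)
    z = np.empty(n_points)
    z[:n_below] = rng.uniform(0.0, 2.0, n_below)
    if n_above:
        mu = float(target_mean_height_m)
        sd = 0.2 * (mu - 2.0) if height_sd_m is None else float(height_sd_m)
        if sd <= 0:
            z[n_below:] = mu
        else:
            lo = (2.01 - mu) / sd
            z[n_below:] = truncnorm.rvs(lo, np.inf, loc=mu, scale=sd,
                                        size=n_above, random_state=rng)
    return pd.DataFrame({"x": x, "y": y, "z": z})
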