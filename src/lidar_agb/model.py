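"""Bayesian geostatistical model for square-root aboveground biomass.

The response is plot-level sqrt(AGB density); the model is

    y(s) = x(s)' beta + w(s) + eps(s)

with w a zero-mean Gaussian process with exponential covariance
``sigma2 * exp(-phi * d)`` (partial sill ``sigma2``, decay ``phi`` in 1/km)
and iid Gaussian nugget ``eps`` with variance ``tau2``.  The null model uses
an intercept-only design.  Sampling marginalizes w analytically
(y ~ N(X beta, sigma2 R(phi) + tau2 I)) and recovers w per retained draw from
its Gaussian conditional, which mixes far better than updating w jointly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import squareform, pdist
from scipy.special import expit, gammaln

logger = logging.getLogger(__name__)

#: -ln(0.05); effective range of the exponential covariance is this over phi.
EFF_RANGE_CONST = -np.log(0.05)

__all__ = [
    "EFF_RANGE_CONST",
    "Priors",
    "MCMCConfig",
    "PosteriorSamples",
    "BiomassGeostatModel",
    "BiomassGeostatResults",
    "exp_covariance",
    "effective_range",
    "log_marginal_likelihood",
    "nugget_to_sill",
]


def exp_covariance(dist_km: np.ndarray, sigma2: float, phi: float) -> np.ndarray:
    """Exponential covariance matrix ``sigma2 * exp(-phi * d)``.

    Parameters
    ----------
    dist_km : symmetric distance matrix with zero diagonal, in km.
    sigma2 : partial sill (variance at distance zero), >= 0.
    phi : spatial decay, > 0 (1/km).
    """
    d = np.asarray(dist_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if d.ndim == 2 and d.shape[0] == d.shape[1]:
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    return sigma2 * np.exp(-phi * d)


def effective_range(phi: float | np.ndarray) -> float | np.ndarray:
    """Distance (km) at which correlation decays to 0.05: -ln(0.05)/phi."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("phi must be > 0")
    out = EFF_RANGE_CONST / phi
    return float(out) if out.ndim == 0 else out


def nugget_to_sill(tau2: float, sigma2: float) -> float:
    """Nugget-to-sill ratio tau2 / (tau2 + sigma2) in [0, 1].

    Small values indicate strong spatial dependence.
    """
    if tau2 < 0 or sigma2 < 0:
        raise ValueError("variance components must be >= 0")
    if tau2 == 0 and sigma2 == 0:
        raise ValueError("tau2 and sigma2 cannot both be zero")
    return tau2 / (tau2 + sigma2)


def _chol_with_jitter(cov: np.ndarray, scale: float):
    """Lower Cholesky factor, retrying with a small diagonal jitter.

    Returns (L, jittered flag).  Raises np.linalg.LinAlgError naming the
    jitter policy when even the jittered matrix fails to factor.
    """
    try:
        return linalg.cholesky(cov, lower=True), False
    except linalg.LinAlgError:
        jitter = 1e-8 * max(scale, 1.0)
        try:
            L = linalg.cholesky(cov + jitter * np.eye(cov.shape[0]), lower=True)
        except linalg.LinAlgError as exc:  # pragma: no cover - pathological
            raise np.linalg.LinAlgError(
                f"covariance factorization failed even with 1e-8*scale "
                f"diagonal jitter ({jitter:.3g})"
            ) from exc
        logger.debug("added diagonal jitter %.3g to covariance", jitter)
        return L, True


def log_marginal_likelihood(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    sigma2: float,
    tau2: float,
    phi: float,
    dist_km: np.ndarray,
) -> float:
    """Gaussian log-density of y ~ N(X beta, sigma2 R(phi) + tau2 I).

    This is the model likelihood with the spatial random effect integrated
    out, evaluated through a Cholesky factorization for stability.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Sigma = exp_covariance(dist_km, sigma2, phi)
    Sigma[np.diag_indices(n)] += tau2
    L, _ = _chol_with_jitter(Sigma, sigma2 + tau2)
    r = y - np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    z = linalg.solve_triangular(L, r, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + z @ z))


@dataclass(frozen=True)
class Priors:
    """Vague priors for the geostatistical model.

    beta ~ N(0, beta_var) independently; sigma2, tau2 ~ inverse-gamma(shape,
    scale) with scale defaulting to half the ordinary-least-squares
    residual variance of y (for the null model that is just the sample
    variance), so the prior scale tracks the variance the spatial terms
    actually have to explain; phi ~ Uniform(phi_lo, phi_hi) with bounds
    derived from the pairwise-distance range of the data (so the effective
    range stays inside the domain).
    """

    beta_var: float = 1e4
    ig_shape: float = 2.0
    ig_scale: float = 1.0
    phi_lo: float = 0.1
    phi_hi: float = 100.0

    def __post_init__(self):
        if self.beta_var <= 0 or self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("prior variances/shapes must be positive")
        if not (0 < self.phi_lo < self.phi_hi):
            raise ValueError("phi bounds must be positive and ordered")

    @classmethod
    def from_data(cls, y: np.ndarray, dist_km: np.ndarray,
                  X: np.ndarray | None = None,
                  min_dist_floor_km: float = 0.03) -> "Priors":
        """Data-derived vague priors (see class docstring)."""
        off = dist_km[np.triu_indices_from(dist_km, k=1)]
        d_max = float(off.max())
        d_min = max(float(off[off > 0].min()) if np.any(off > 0) else
                    min_dist_floor_km, min_dist_floor_km)
        if X is not None:
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            resid_var = float(np.var(y - X @ beta))
        else:
            resid_var = float(np.var(y))
        return cls(
            ig_scale=max(0.5 * resid_var, 1e-6),
            phi_lo=EFF_RANGE_CONST / d_max,
            phi_hi=EFF_RANGE_CONST / d_min,
        )


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings for the adaptive Metropolis-within-Gibbs sampler."""

    n_iter: int = 25_000
    n_burn: int = 5_000
    thin: int = 10
    proposal_scale: float = 0.5
    adapt: bool = True
    target_accept: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.n_burn < self.n_iter):
            raise ValueError("need 0 <= n_burn < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin


@dataclass
class PosteriorSamples:
    """Retained MCMC draws for the geostatistical model.

    w draws at the plot locations are recovered lazily (see
    BiomassGeostatResults.recover_w) from the Gaussian conditional of the
    marginalized spatial effect given each retained (beta, theta) draw.
    """

    beta: np.ndarray          # (T, p)
    sigma2: np.ndarray        # (T,)
    tau2: np.ndarray          # (T,)
    phi: np.ndarray           # (T,)
    acceptance_rate: float
    beta_names: list[str] = field(default_factory=list)
    w: np.ndarray | None = None  # (T, n) once recovered

    @property
    def eff_range_km(self) -> np.ndarray:
        return EFF_RANGE_CONST / self.phi

    @property
    def n_draws(self) -> int:
        return self.sigma2.size


def _log_ig(x: float, shape: float, scale: float) -> float:
    return shape * np.log(scale) - gammaln(shape) - (shape + 1) * np.log(x) - scale / x


class BiomassGeostatModel:
    """Bayesian geostatistical regression of sqrt(AGB) on lidar metrics.

    Parameters
    ----------
    y_sqrt : (n,) response, sqrt of plot AGB density in sqrt(Mg/ha).
    coords_km : (n, 2) plot coordinates in a planar km system.
    X : optional (n, k) covariate matrix (lidar metrics, no intercept
        column); omit for the null (intercept-only) spatial model.
    priors : optional Priors; defaults are derived from the data.
    metric_names : labels for the covariate columns.

    Exact duplicate locations are jittered by 1 m with a warning: at tau2
    -> 0 duplicates make the marginal covariance singular.
    """

    def __init__(self, y_sqrt, coords_km, X=None, priors: Priors | None = None,
                 metric_names: list[str] | None = None):
        y = np.asarray(y_sqrt, dtype=float).ravel()
        coords = np.asarray(coords_km, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords_km must be (n, 2)")
        if y.size != coords.shape[0]:
            raise ValueError("y and coords length mismatch")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(coords))):
            raise ValueError("non-finite response or coordinates")
        if y.size < 10:
            raise ValueError("need at least 10 plots")

        coords = self._jitter_duplicates(coords)
        self.coords_km = coords
        self.y = y
        self.n = y.size
        if X is None:
            self.kind = "null"
            self.X = np.ones((self.n, 1))
            self.beta_names = ["beta_0"]
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if X.shape[0] != self.n:
                raise ValueError("X row count must match y")
            if not np.all(np.isfinite(X)):
                raise ValueError("non-finite covariates")
            self.kind = "covariate"
            self.X = np.column_stack([np.ones(self.n), X])
            names = metric_names or [f"x{i + 1}" for i in range(X.shape[1])]
            self.beta_names = ["beta_0"] + [f"beta_{nm}" for nm in names]
        self.metric_names = metric_names or []
        self.dist_km = squareform(pdist(coords))
        self.priors = (priors if priors is not None
                       else Priors.from_data(y, self.dist_km, X=self.X))

    @classmethod
    def from_dataframe(cls, plots: pd.DataFrame, metrics: pd.DataFrame | None = None,
                       metric_names: list[str] | None = None,
                       priors: Priors | None = None) -> "BiomassGeostatModel":
        """Build from a plot table (x_km, y_km, agb_sqrt or agb_mg_ha) and an
        optional aligned metric table restricted to ``metric_names``."""
        if "agb_sqrt" in plots.columns:
            y = plots["agb_sqrt"].to_numpy(dtype=float)
        else:
            y = np.sqrt(plots["agb_mg_ha"].to_numpy(dtype=float))
        coords = plots[["x_km", "y_km"]].to_numpy(dtype=float)
        X = None
        if metrics is not None:
            if metric_names is None:
                raise ValueError("metric_names required with a metric table")
            if len(metrics) != len(plots):
                raise ValueError("metric table row count must equal plot count")
            X = metrics[list(metric_names)].to_numpy(dtype=float)
        return cls(y, coords, X=X, priors=priors, metric_names=metric_names)

    @staticmethod
    def _jitter_duplicates(coords: np.ndarray) -> np.ndarray:
        _, inverse, counts = np.unique(coords, axis=0, return_inverse=True,
                                       return_counts=True)
        if np.any(counts > 1):
            warnings.warn("duplicate plot locations jittered by 1 m",
                          UserWarning, stacklevel=3)
            coords = coords.copy()
            seen: dict[int, int] = {}
            rng = np.random.default_rng(0)
            for i, g in enumerate(inverse):
                k = seen.get(g, 0)
                seen[g] = k + 1
                if k > 0:
                    ang = rng.uniform(0, 2 * np.pi)
                    coords[i] += 0.001 * np.array([np.cos(ang), np.sin(ang)])
        return coords

    # -- sampler internals -------------------------------------------------

    def _sigma_factor(self, sigma2, tau2, phi):
        Sigma = sigma2 * np.exp(-phi * self.dist_km)
        Sigma[np.diag_indices(self.n)] += tau2
        return _chol_with_jitter(Sigma, sigma2 + tau2)[0]

    def _loglik(self, beta, L):
        r = self.y - self.X @ beta
        z = linalg.solve_triangular(L, r, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        return -0.5 * (self.n * np.log(2 * np.pi) + logdet + z @ z)

    def _log_prior_u(self, u):
        """Prior + Jacobian on the transformed scale u = (log s2, log t2, z)."""
        pr = self.priors
        s2, t2 = np.exp(u[0]), np.exp(u[1])
        lp = _log_ig(s2, pr.ig_shape, pr.ig_scale) + u[0]
        lp += _log_ig(t2, pr.ig_shape, pr.ig_scale) + u[1]
        # uniform phi density is constant; keep the logit Jacobian
        s = expit(u[2])
        lp += np.log(pr.phi_hi - pr.phi_lo) + np.log(s) + np.log1p(-s)
        return lp

    def _phi_of(self, z):
        return self.priors.phi_lo + (self.priors.phi_hi - self.priors.phi_lo) * expit(z)

    def _draw_beta(self, L, rng):
        """Gibbs draw of beta from its conjugate Gaussian conditional."""
        A = linalg.cho_solve((L, True), self.X)          # Sigma^{-1} X
        Vinv = self.X.T @ A + np.eye(self.X.shape[1]) / self.priors.beta_var
        Lv = linalg.cholesky(Vinv, lower=True)
        b = A.T @ self.y
        mean = linalg.cho_solve((Lv, True), b)
        z = rng.standard_normal(b.size)
        return mean + linalg.solve_triangular(Lv, z, lower=True, trans=1)

    def fit(self, n_iter: int = 25_000, n_burn: int = 5_000, thin: int = 10,
            seed: int = 0, config: MCMCConfig | None = None,
            progress: bool = False) -> "BiomassGeostatResults":
        """Run the MCMC sampler and return a results object.

        The covariance parameters move on unconstrained scales (log sigma2,
        log tau2, logit-scaled phi) under a joint adaptive random-walk
        Metropolis step; beta is Gibbs-updated from its Gaussian conditional
        under the marginalized likelihood.  Bit-reproducible given ``seed``.
        """
        cfg = config or MCMCConfig(n_iter=n_iter, n_burn=n_burn, thin=thin, seed=seed)
        seq = np.random.SeedSequence(cfg.seed)
        chain_seed, w_seed = seq.spawn(2)
        rng = np.random.default_rng(chain_seed)
        pr = self.priors

        # initial values: OLS beta, variance split, mid-prior phi
        beta = np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        resid_var = max(float(np.var(self.y - self.X @ beta)), 1e-6)
        u = np.array([
            np.log(0.75 * resid_var),
            np.log(0.25 * resid_var),
            0.0,
        ])
        L = self._sigma_factor(np.exp(u[0]), np.exp(u[1]), self._phi_of(u[2]))
        logpost = self._loglik(beta, L) + self._log_prior_u(u)
        if not np.isfinite(logpost):
            raise RuntimeError("divergent chain: non-finite initial log-posterior")

        step = cfg.proposal_scale
        comp = np.array([0.4, 0.8, 0.6])  # relative scales for (ls2, lt2, z-phi)
        n_keep = cfg.n_retained
        p = self.X.shape[1]
        out_beta = np.empty((n_keep, p))
        out_s2 = np.empty(n_keep)
        out_t2 = np.empty(n_keep)
        out_phi = np.empty(n_keep)
        n_acc = 0
        n_prop = 0
        kept = 0

        for it in range(cfg.n_iter):
            # Metropolis update of the covariance parameters
            u_prop = u + step * comp * rng.standard_normal(3)
            s2p, t2p = np.exp(u_prop[0]), np.exp(u_prop[1])
            phip = self._phi_of(u_prop[2])
            Lp = self._sigma_factor(s2p, t2p, phip)
            lp_prop = self._loglik(beta, Lp) + self._log_prior_u(u_prop)
            n_prop += 1
            accept = np.log(rng.uniform()) < lp_prop - logpost
            if accept:
                u, L, logpost = u_prop, Lp, lp_prop
                n_acc += 1
            if cfg.adapt and it < cfg.n_burn:
                gamma = min(0.2, 3.0 / np.sqrt(it + 1.0))
                step *= np.exp(gamma * ((1.0 if accept else 0.0) - cfg.target_accept))

            # Gibbs update of beta, then refresh the cached log-posterior
            beta = self._draw_beta(L, rng)
            logpost = self._loglik(beta, L) + self._log_prior_u(u)
            if not np.isfinite(logpost):
                raise RuntimeError(f"divergent chain at iteration {it}")

            if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0 and kept < n_keep:
                out_beta[kept] = beta
                out_s2[kept] = np.exp(u[0])
                out_t2[kept] = np.exp(u[1])
                out_phi[kept] = self._phi_of(u[2])
                kept += 1

        acc_rate = n_acc / max(n_prop, 1)
        if not (0.1 <= acc_rate <= 0.7):
            warnings.warn(
                f"Metropolis acceptance rate {acc_rate:.2f} outside [0.1, 0.7] "
                "after adaptation; inspect the chain", UserWarning)
        samples = PosteriorSamples(
            beta=out_beta[:kept], sigma2=out_s2[:kept], tau2=out_t2[:kept],
            phi=out_phi[:kept], acceptance_rate=acc_rate,
            beta_names=list(self.beta_names))
        return BiomassGeostatResults(self, samples, cfg, w_seed)


def summarize_posterior(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior quantile table: median with (2.5%, 97.5%) per parameter,
    including the derived effective range in km."""
    if samples.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    rows = {}
    for j, nm in enumerate(samples.beta_names):
        rows[nm] = samples.beta[:, j]
    rows["tau2"] = samples.tau2
    rows["sigma2"] = samples.sigma2
    rows["phi"] = samples.phi
    rows["eff_range_km"] = samples.eff_range_km
    table = pd.DataFrame(
        {
            "50%": {k: np.median(v) for k, v in rows.items()},
            "2.5%": {k: np.quantile(v, 0.025) for k, v in rows.items()},
            "97.5%": {k: np.quantile(v, 0.975) for k, v in rows.items()},
        }
    )
    table.index.name = "parameter"
    return table


class BiomassGeostatResults:
    """Posterior draws plus derived quantities for a fitted model.

    Provides the quantile summary table, lazy recovery of the spatial random
    effect at the plot locations, and composition-sampled posterior
    predictive AGB at new locations (see lidar_agb.predict).
    """

    def __init__(self, model: BiomassGeostatModel, samples: PosteriorSamples,
                 config: MCMCConfig, w_seed: np.random.SeedSequence):
        self.model = model
        self.samples = samples
        self.config = config
        self._w_seed = w_seed

    # convenience accessors -------------------------------------------------
    @property
    def kind(self) -> str:
        return self.model.kind

    @property
    def acceptance_rate(self) -> float:
        return self.samples.acceptance_rate

    def posterior_median(self, name: str) -> float:
        s = self.samples
        table = {"sigma2": s.sigma2, "tau2": s.tau2, "phi": s.phi,
                 "eff_range_km": s.eff_range_km}
        if name in table:
            return float(np.median(table[name]))
        j = s.beta_names.index(name)
        return float(np.median(s.beta[:, j]))

    def nugget_to_sill(self) -> float:
        """Ratio of posterior-median nugget to median total sill."""
        return nugget_to_sill(self.posterior_median("tau2"),
                              self.posterior_median("sigma2"))

    def summary(self) -> pd.DataFrame:
        return summarize_posterior(self.samples)

    def summary_text(self) -> str:
        t = self.summary()
        lines = [f"Biomass geostatistical model ({self.kind}), "
                 f"n={self.model.n}, draws={self.samples.n_draws}, "
                 f"acceptance={self.acceptance_rate:.2f}"]
        for nm, row in t.iterrows():
            lines.append(f"  {nm:>16s}  {row['50%']:8.3f} "
                         f"({row['2.5%']:.3f}, {row['97.5%']:.3f})")
        return "\n".join(lines)

    def plot_trace(self, params=("sigma2", "tau2", "phi"), axes=None):
        """Trace plots of retained draws for quick mixing checks."""
        import matplotlib.pyplot as plt

        s = self.samples
        series = {"sigma2": s.sigma2, "tau2": s.tau2, "phi": s.phi,
                  "eff_range_km": s.eff_range_km}
        series.update({nm: s.beta[:, j] for j, nm in enumerate(s.beta_names)})
        params = list(params)
        if axes is None:
            _, axes = plt.subplots(len(params), 1, sharex=True,
                                   figsize=(7, 1.8 * len(params)))
        axes = np.atleast_1d(axes)
        for ax, nm in zip(axes, params):
            ax.plot(series[nm], lw=0.6)
            ax.set_ylabel(nm)
        axes[-1].set_xlabel("retained draw")
        return axes

    # spatial-effect recovery ----------------------------------------------
    def recover_w(self) -> np.ndarray:
        """Draw w at the plot locations, one draw per retained parameter draw.

        w | y, beta, theta ~ N(S Sigma^-1 r, S - S Sigma^-1 S) with
        S = sigma2 R(phi), Sigma = S + tau2 I, r = y - X beta.  Cached.
        """
        if self.samples.w is not None:
            return self.samples.w
        m = self.model
        s = self.samples
        rng = np.random.default_rng(self._w_seed)
        T = s.n_draws
        W = np.empty((T, m.n))
        eye = np.eye(m.n)
        for t in range(T):
            S = s.sigma2[t] * np.exp(-s.phi[t] * m.dist_km)
            Sigma = S + s.tau2[t] * eye
            L = _chol_with_jitter(Sigma, s.sigma2[t] + s.tau2[t])[0]
            r = m.y - m.X @ s.beta[t]
            SinvS = linalg.cho_solve((L, True), S)
            mean = SinvS.T @ r
            C = S - S @ SinvS
            Lc = _chol_with_jitter(
                C + 1e-10 * max(s.sigma2[t], 1.0) * eye, s.sigma2[t])[0]
            W[t] = mean + Lc @ rng.standard_normal(m.n)
        s.w = W
        return W

    def predict(self, coords_km, metrics=None, seed: int = 0,
                mode: str = "independent", include_nugget: bool = True):
        """Composition-sample the posterior predictive AGB distribution at
        new locations; see lidar_agb.predict.composition_predict."""
        from .predict import BiomassPrediction, composition_predict

        coords = np.asarray(coords_km, dtype=float)
        if self.kind == "null":
            design = np.ones((coords.shape[0], 1))
        else:
            if metrics is None:
                raise ValueError("covariate model prediction needs metric values")
            M = (metrics[list(self.model.metric_names)].to_numpy(dtype=float)
                 if isinstance(metrics, pd.DataFrame)
                 else np.asarray(metrics, dtype=float))
            if not np.all(np.isfinite(M)):
                raise ValueError("missing metric values at prediction locations")
            design = np.column_stack([np.ones(coords.shape[0]), M])
        sqrt_draws = composition_predict(
            self.samples, self.recover_w(), self.model.coords_km, coords,
            design, seed=seed, mode=mode, include_nugget=include_nugget)
        return BiomassPrediction(sqrt_draws, coords)
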