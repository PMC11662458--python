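"""Ten-fold holdout cross-validation and map-comparison error metrics.

Plots are randomly partitioned into k near-equal folds; each fold is held
out in turn while the model is refitted on the remainder and the holdouts
are composition-predicted, back-transformed and summarized, so every plot
receives exactly one out-of-sample predictive distribution.  The report
combines point-error metrics (RMSE, relative squared error, squared
Pearson R^2, bias) with calibration metrics (empirical 95% coverage
probability and mean credible-interval width).

RSE here is relative SQUARED error, 100 * sum((est-obs)^2) /
sum((obs-mean(obs))^2) — the ratio of prediction error to the variance a
mean-only predictor leaves unexplained, so a skill-free model scores near
(or above) 100%.  R^2 is the squared Pearson correlation of observed and
predicted values.  The point estimate entering the error metrics is the
back-transformed predictive median (Est).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BiomassGeostatModel, MCMCConfig, Priors
from .predict import back_transform, summarize_pixels

__all__ = ["ValidationReport", "kfold_split", "cv_run", "compute_metrics",
           "compare_to_map"]


@dataclass(frozen=True)
class ValidationReport:
    rmse: float            # Mg/ha
    rse_pct: float
    r2: float
    bias: float            # Mg/ha, mean(predicted - observed)
    coverage_pct: float    # share of obs inside their 95% CI
    mean_ci_width: float   # Mg/ha
    n: int

    def to_dict(self) -> dict:
        return {
            "rmse_mg_ha": self.rmse, "rse_pct": self.rse_pct, "r2": self.r2,
            "bias_mg_ha": self.bias, "coverage_pct": self.coverage_pct,
            "mean_ci_width_mg_ha": self.mean_ci_width, "n": self.n,
        }


def kfold_split(n_plots: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random fold labels 0..k-1; fold sizes differ by at most one."""
    if k > n_plots:
        raise ValueError("k must not exceed the number of plots")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_plots) % k
    return labels[rng.permutation(n_plots)]


def cv_run(plots: pd.DataFrame, metrics: pd.DataFrame | None,
           metric_names=None, priors: Priors | None = None,
           mcmc: MCMCConfig | None = None, k: int = 10,
           seed: int = 0) -> pd.DataFrame:
    """Per-plot holdout predictive summaries from k-fold cross-validation.

    Returns one row per plot: obs (Mg/ha), est, sd, ci_lo, ci_hi, fold,
    covered.  The fit within each fold uses the supplied chain settings
    (defaults otherwise); all randomness descends from ``seed``.
    """
    n = len(plots)
    folds = kfold_split(n, k=k, seed=seed)
    mcmc = mcmc or MCMCConfig()
    seq = np.random.SeedSequence(seed)
    fit_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seq.spawn(2 * k)]

    obs = plots["agb_mg_ha"].to_numpy(dtype=float)
    rows = np.empty((n, 4))
    for f in range(k):
        test = folds == f
        train = ~test
        train_plots = plots.loc[train]
        train_metrics = metrics.loc[train] if metrics is not None else None
        model = BiomassGeostatModel.from_dataframe(
            train_plots, train_metrics, metric_names=metric_names,
            priors=priors)
        cfg = MCMCConfig(n_iter=mcmc.n_iter, n_burn=mcmc.n_burn,
                         thin=mcmc.thin, proposal_scale=mcmc.proposal_scale,
                         adapt=mcmc.adapt, target_accept=mcmc.target_accept,
                         seed=fit_seeds[2 * f])
        try:
            res = model.fit(config=cfg)
        except RuntimeError as exc:
            raise RuntimeError(f"cross-validation fold {f} failed: {exc}") from exc
        coords = plots.loc[test, ["x_km", "y_km"]].to_numpy(dtype=float)
        test_metrics = metrics.loc[test] if metrics is not None else None
        pred = res.predict(coords, test_metrics, seed=fit_seeds[2 * f + 1])
        summ = summarize_pixels(pred.agb_draws)
        rows[test, 0] = summ["est"].to_numpy()
        rows[test, 1] = summ["sd"].to_numpy()
        rows[test, 2] = summ["ci_lo"].to_numpy()
        rows[test, 3] = summ["ci_hi"].to_numpy()

    out = plots[["plot_id"]].copy() if "plot_id" in plots.columns else pd.DataFrame(
        index=plots.index)
    out["obs"] = obs
    out["est"] = rows[:, 0]
    out["sd"] = rows[:, 1]
    out["ci_lo"] = rows[:, 2]
    out["ci_hi"] = rows[:, 3]
    out["fold"] = folds
    out["covered"] = (obs >= rows[:, 2]) & (obs <= rows[:, 3])
    return out.reset_index(drop=True)


def compute_metrics(obs, est, ci_lo, ci_hi) -> ValidationReport:
    """Error and calibration metrics for paired observations/predictions."""
    obs = np.asarray(obs, dtype=float)
    est = np.asarray(est, dtype=float)
    ci_lo = np.asarray(ci_lo, dtype=float)
    ci_hi = np.asarray(ci_hi, dtype=float)
    if not (obs.size == est.size == ci_lo.size == ci_hi.size):
        raise ValueError("input vectors must have equal length")
    if np.any(ci_lo > ci_hi):
        raise ValueError("credible bounds must be ordered")
    n = obs.size
    err = est - obs
    rmse = float(np.sqrt(np.mean(err ** 2)))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    rse = float(100.0 * np.sum(err ** 2) / sst) if sst > 0 else np.nan
    if sst > 0 and np.std(est) > 0:
        r2 = float(np.corrcoef(obs, est)[0, 1] ** 2)
    else:
        r2 = np.nan  # undefined for a constant vector
    bias = float(np.mean(err))
    covered = (obs >= ci_lo) & (obs <= ci_hi)
    coverage = float(100.0 * covered.sum() / n)
    width = float(np.mean(ci_hi - ci_lo))
    return ValidationReport(rmse=rmse, rse_pct=rse, r2=r2, bias=bias,
                            coverage_pct=coverage, mean_ci_width=width, n=n)


def compare_to_map(obs, map_values) -> dict:
    """Error metrics plus the obs-vs-pred straight line for an external map.

    The line is an ordinary least-squares fit of the map prediction on the
    observation (prediction as response); a slope below 1 is the
    regression-to-the-mean signature of a shrunken map product.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(map_values, dtype=float)
    if obs.size != pred.size:
        raise ValueError("paired vectors must have equal length")
    if obs.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("non-finite values in comparison")
    err = pred - obs
    sst = float(np.sum((obs - obs.mean()) ** 2))
    slope, intercept = np.polyfit(obs, pred, 1)
    return {
        "rmse_mg_ha": float(np.sqrt(np.mean(err ** 2))),
        "rse_pct": float(100.0 * np.sum(err ** 2) / sst) if sst > 0 else np.nan,
        "bias_mg_ha": float(np.mean(err)),
        "slope": float(slope),
        "intercept": float(intercept),
        "n": int(obs.size),
    }
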