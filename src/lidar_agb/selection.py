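"""Exhaustive 2- and 3-metric OLS search for sqrt(AGB) predictors.

All C(k,2) + C(k,3) metric subsets are fitted by ordinary least squares
with an intercept and ranked by adjusted R^2 (ties broken by lower AIC,
then smaller subset, then lexicographic names).  Collinearity among the
selected metrics is allowed — structure metrics are naturally correlated
and the winning trio typically is.

AIC convention: -2 logL + 2 (p + 2), counting the intercept and the
residual variance as parameters, with the Gaussian log-likelihood
evaluated at the maximum-likelihood variance SSE/n.  Only relative
ranking matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ModelCandidate", "SelectionResult", "enumerate_candidates",
           "fit_ols", "select_best"]


@dataclass(frozen=True)
class ModelCandidate:
    metric_subset: tuple[str, ...]
    coefficients: tuple[float, ...]  # intercept first
    r2: float
    adjusted_r2: float
    aic: float
    rank: int | None = None


class RankDeficientError(ValueError):
    pass


def enumerate_candidates(metric_names) -> list[tuple[str, ...]]:
    """All size-2 and size-3 subsets in deterministic (size, lexicographic)
    order; input order does not matter."""
    names = list(metric_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate metric names")
    if len(names) < 3:
        raise ValueError("need at least 3 distinct metric names")
    names = sorted(names)
    return list(combinations(names, 2)) + list(combinations(names, 3))


def fit_ols(y, X, names=None):
    """Least-squares fit of y on [1, X]; returns (coef, r2, adj_r2, aic).

    Raises RankDeficientError naming the collinear columns when the design
    is rank-deficient, and ValueError when n <= p + 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < p + 1:
        cols = list(names) if names is not None else [f"x{i+1}" for i in range(p)]
        raise RankDeficientError(f"rank-deficient design; collinear columns "
                                 f"among {cols}")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    sig2 = max(sse / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sig2) + 1.0)
    aic = -2.0 * loglik + 2.0 * (p + 2)
    return coef, r2, adj, aic


def select_best(y_sqrt, metric_table: pd.DataFrame,
                metric_names=None) -> "SelectionResult":
    """Fit every 2-/3-metric candidate and rank them.

    Candidates that fail to fit (rank deficiency) are recorded as failed,
    excluded from the ranking, and logged.  Missing metric values raise.
    """
    names = list(metric_names) if metric_names is not None else [
        c for c in metric_table.columns if c != "plot_id"]
    M = metric_table[names]
    if M.isna().any().any():
        raise ValueError("missing metric values among plots")
    y = np.asarray(y_sqrt, dtype=float).ravel()
    rows = []
    failed = []
    for subset in enumerate_candidates(names):
        X = M[list(subset)].to_numpy(dtype=float)
        try:
            coef, r2, adj, aic = fit_ols(y, X, names=subset)
        except (RankDeficientError, ValueError) as exc:
            failed.append(subset)
            logger.warning("candidate %s failed: %s", subset, exc)
            continue
        rows.append(ModelCandidate(subset, tuple(coef), r2, adj, aic))
    # rank: adjusted R^2 desc; ties by AIC asc, smaller subset, lexicographic
    rows.sort(key=lambda c: (-c.adjusted_r2, c.aic, len(c.metric_subset),
                             c.metric_subset))
    ranked = [ModelCandidate(c.metric_subset, c.coefficients, c.r2,
                             c.adjusted_r2, c.aic, rank=i + 1)
              for i, c in enumerate(rows)]
    return SelectionResult(ranked, failed)


class SelectionResult:
    """Full candidate ranking; .best is the top candidate."""

    def __init__(self, candidates: list[ModelCandidate], failed):
        self.candidates = candidates
        self.failed = failed

    @property
    def best(self) -> ModelCandidate:
        return self.candidates[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"rank": c.rank, "metrics": "+".join(c.metric_subset),
             "n_metrics": len(c.metric_subset), "r2": c.r2,
             "adjusted_r2": c.adjusted_r2, "aic": c.aic}
            for c in self.candidates])

    def best_subset(self) -> list[str]:
        return list(self.best.metric_subset)
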