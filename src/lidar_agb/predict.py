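"""Posterior predictive AGB at new locations by composition sampling.

For each retained posterior draw (beta, sigma2, tau2, phi, w) the spatial
effect at a new site is drawn from the Gaussian process conditional given
the w draw at the plot sites,

    w0 | w ~ N(r0' R^-1 w, sigma2 (1 - r0' R^-1 r0)),

then y0 = x0' beta + w0 + N(0, tau2) on the sqrt scale.  Squaring the draws
(including negative ones) gives the AGB-density predictive distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg

from .model import PosteriorSamples, _chol_with_jitter

__all__ = ["composition_predict", "back_transform", "summarize_pixels",
           "BiomassPrediction"]

#: pixels per linear-algebra block; results are invariant to this value
#: because all random variates are drawn up front in fixed pixel order.
BLOCK_SIZE = 1024


def composition_predict(
    samples: PosteriorSamples,
    w_draws: np.ndarray,
    plot_coords_km: np.ndarray,
    new_coords_km: np.ndarray,
    new_design: np.ndarray,
    seed: int = 0,
    mode: str = "independent",
    include_nugget: bool = True,
) -> np.ndarray:
    """Sqrt-scale posterior predictive draw matrix (draws x locations).

    mode="independent" draws new-site spatial effects conditionally
    independently across pixels given each w draw (tractable for large
    grids, slightly understates cross-pixel dependence); mode="joint" draws
    them jointly from the full conditional (limited to <= 2000 locations).
    """
    new_coords = np.atleast_2d(np.asarray(new_coords_km, dtype=float))
    plot_coords = np.asarray(plot_coords_km, dtype=float)
    X0 = np.atleast_2d(np.asarray(new_design, dtype=float))
    m = new_coords.shape[0]
    n = plot_coords.shape[0]
    if X0.shape[0] != m:
        raise ValueError("design rows must match prediction locations")
    if not np.all(np.isfinite(X0)):
        raise ValueError("missing metric values in prediction design")
    if mode not in ("independent", "joint"):
        raise ValueError("mode must be 'independent' or 'joint'")
    if mode == "joint" and m > 2000:
        raise ValueError("joint mode is limited to 2000 locations")

    T = samples.n_draws
    rng = np.random.default_rng(seed)
    # all variates drawn up front in fixed (draw, pixel) order so that the
    # block partitioning below cannot change the result
    z_w = rng.standard_normal((T, m))
    z_eps = rng.standard_normal((T, m)) if include_nugget else np.zeros((T, m))

    d_pp = np.linalg.norm(plot_coords[:, None, :] - plot_coords[None, :, :], axis=-1)
    d_pn = np.linalg.norm(plot_coords[:, None, :] - new_coords[None, :, :], axis=-1)
    if mode == "joint":
        d_nn = np.linalg.norm(new_coords[:, None, :] - new_coords[None, :, :], axis=-1)

    out = np.empty((T, m))
    for t in range(T):
        phi = samples.phi[t]
        s2 = samples.sigma2[t]
        t2 = samples.tau2[t]
        R = np.exp(-phi * d_pp)
        L = _chol_with_jitter(R + 1e-10 * np.eye(n), 1.0)[0]
        a = linalg.cho_solve((L, True), w_draws[t])
        trend = X0 @ samples.beta[t]
        if mode == "independent":
            for lo in range(0, m, BLOCK_SIZE):
                hi = min(lo + BLOCK_SIZE, m)
                r0 = np.exp(-phi * d_pn[:, lo:hi])
                mean_w = r0.T @ a
                B = linalg.cho_solve((L, True), r0)
                var_w = s2 * np.clip(1.0 - np.einsum("ij,ij->j", r0, B), 0.0, None)
                out[t, lo:hi] = (trend[lo:hi] + mean_w
                                 + np.sqrt(var_w) * z_w[t, lo:hi])
        else:
            r0 = np.exp(-phi * d_pn)
            mean_w = r0.T @ a
            B = linalg.cho_solve((L, True), r0)
            C = s2 * (np.exp(-phi * d_nn) - r0.T @ B)
            Lc = _chol_with_jitter(C + 1e-10 * max(s2, 1.0) * np.eye(m), s2)[0]
            out[t] = trend + mean_w + Lc @ z_w[t]
        if include_nugget:
            out[t] += np.sqrt(t2) * z_eps[t]
    return out


def back_transform(sqrt_draws: np.ndarray) -> np.ndarray:
    """Square sqrt-scale draws elementwise to AGB density (Mg/ha).

    Negative sqrt-scale draws are squared as-is (no truncation), so the
    implied AGB distribution is always non-negative.
    """
    sqrt_draws = np.asarray(sqrt_draws, dtype=float)
    if not np.all(np.isfinite(sqrt_draws)):
        raise ValueError("non-finite sqrt-scale draws")
    return np.square(sqrt_draws)


def summarize_pixels(agb_draws: np.ndarray) -> pd.DataFrame:
    """Per-pixel predictive summaries of back-transformed AGB draws.

    Columns: est (median, Mg/ha), sd, rsd_pct (100*sd/est, NaN where est is
    0), ci_lo and ci_hi (2.5% / 97.5% quantiles).  Requires >= 100 draws.
    """
    A = np.atleast_2d(np.asarray(agb_draws, dtype=float))
    if A.shape[0] < 100:
        raise ValueError("need at least 100 draws per pixel")
    est = np.median(A, axis=0)
    sd = np.std(A, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(est > 0, 100.0 * sd / est, np.nan)
    return pd.DataFrame({
        "est": est,
        "sd": sd,
        "rsd_pct": rsd,
        "ci_lo": np.quantile(A, 0.025, axis=0),
        "ci_hi": np.quantile(A, 0.975, axis=0),
    })


class BiomassPrediction:
    """Composition-sampled predictive distribution at a set of locations."""

    def __init__(self, sqrt_draws: np.ndarray, coords_km: np.ndarray):
        self.sqrt_draws = sqrt_draws
        self.coords_km = coords_km
        self._agb = None

    @property
    def agb_draws(self) -> np.ndarray:
        if self._agb is None:
            self._agb = back_transform(self.sqrt_draws)
        return self._agb

    def summary(self) -> pd.DataFrame:
        out = summarize_pixels(self.agb_draws)
        out.insert(0, "x_km", self.coords_km[:, 0])
        out.insert(1, "y_km", self.coords_km[:, 1])
        return out

    def plot_map(self, value: str = "est", ax=None, **scatter_kw):
        """Scatter map of a predictive summary (est, sd, rsd_pct, ci_lo,
        ci_hi) at the prediction locations."""
        import matplotlib.pyplot as plt

        summ = summarize_pixels(self.agb_draws)
        if ax is None:
            _, ax = plt.subplots()
        scatter_kw.setdefault("s", 12)
        scatter_kw.setdefault("marker", "s")
        pts = ax.scatter(self.coords_km[:, 0], self.coords_km[:, 1],
                         c=summ[value], **scatter_kw)
        ax.set_xlabel("x (km)")
        ax.set_ylabel("y (km)")
        ax.set_aspect("equal")
        label = {"est": "AGB Est (Mg/ha)", "sd": "AGB SD (Mg/ha)",
                 "rsd_pct": "RSD (%)"}.get(value, value)
        plt.colorbar(pts, ax=ax, label=label)
        return ax
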