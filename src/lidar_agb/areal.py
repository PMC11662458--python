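"""Management-unit totals from pixel-level predictive draws.

Aggregation always works on per-draw pixel values, never on pixel
summaries: per posterior draw, MU mean density is the average over the
unit's unmasked pixels and the total is that density times the unit area,
so the full predictive distribution of the areal quantities (and hence
their credible intervals) is carried through.  Summing pixel medians would
understate the spread and bias the total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ArealEstimate", "mu_joint_estimate", "mg_to_tg", "PIXEL_AREA_HA"]

#: area of one 30 m pixel in hectares.
PIXEL_AREA_HA = 0.09


def mg_to_tg(total_mg: float) -> float:
    """Megagrams to teragrams (divide by 1e6)."""
    if total_mg < 0:
        raise ValueError("total must be >= 0")
    return total_mg / 1e6


@dataclass(frozen=True)
class ArealEstimate:
    """PPD summary for one management unit.

    total_tg / mean_mg_ha are predictive medians with 95% credible bounds;
    rsd_pct (100 * SD / median) is identical for total and mean because
    both are the same draws scaled by the unit area.
    """

    mu_id: object
    n_pixels: int
    area_ha: float
    mean_mg_ha: float
    mean_ci: tuple[float, float]
    mean_sd: float
    total_tg: float
    total_ci: tuple[float, float]
    total_sd_tg: float
    rsd_pct: float

    def to_dict(self) -> dict:
        return {
            "mu_id": self.mu_id, "n_pixels": self.n_pixels,
            "area_ha": self.area_ha,
            "mean_mg_ha": self.mean_mg_ha,
            "mean_ci_lo": self.mean_ci[0], "mean_ci_hi": self.mean_ci[1],
            "mean_sd": self.mean_sd,
            "total_tg": self.total_tg,
            "total_ci_lo": self.total_ci[0], "total_ci_hi": self.total_ci[1],
            "total_sd_tg": self.total_sd_tg,
            "rsd_pct": self.rsd_pct,
        }


def mu_joint_estimate(agb_draws: np.ndarray, mu_ids,
                      pixel_area_ha: float = PIXEL_AREA_HA,
                      areas_ha: dict | None = None) -> pd.DataFrame:
    """Summarize MU-level predictive distributions.

    Parameters
    ----------
    agb_draws : (T, m) back-transformed AGB draws over all pixels, one
        column per pixel, sharing the draw index.
    mu_ids : length-m labels; pixels with a null label (NaN/None) are
        outside every unit.
    pixel_area_ha : area of one pixel (0.09 ha for 30 m cells); the MU area
        is pixel count times this unless an external printed area is
        supplied via ``areas_ha`` (mapping mu_id -> ha), in which case
        totals are reported against that area.
    """
    A = np.atleast_2d(np.asarray(agb_draws, dtype=float))
    ids = np.asarray(mu_ids)
    if ids.size != A.shape[1]:
        raise ValueError("mu_ids length must match the pixel dimension of "
                         "the draw matrix")
    valid = pd.notna(ids)
    out = []
    for mu in pd.unique(ids[valid]):
        sel = valid & (ids == mu)
        n_pix = int(sel.sum())
        if n_pix == 0:
            raise ValueError(f"management unit {mu!r} has no pixels")
        area = (float(areas_ha[mu]) if areas_ha and mu in areas_ha
                else n_pix * pixel_area_ha)
        mean_draws = A[:, sel].mean(axis=1)           # per-draw mean density
        total_draws_tg = mean_draws * area / 1e6      # per-draw total, Tg
        med = float(np.median(mean_draws))
        sd = float(np.std(mean_draws, ddof=1))
        out.append(ArealEstimate(
            mu_id=mu, n_pixels=n_pix, area_ha=area,
            mean_mg_ha=med,
            mean_ci=(float(np.quantile(mean_draws, 0.025)),
                     float(np.quantile(mean_draws, 0.975))),
            mean_sd=sd,
            total_tg=float(np.median(total_draws_tg)),
            total_ci=(float(np.quantile(total_draws_tg, 0.025)),
                      float(np.quantile(total_draws_tg, 0.975))),
            total_sd_tg=float(np.std(total_draws_tg, ddof=1)),
            rsd_pct=float(100.0 * sd / med) if med > 0 else np.nan,
        ).to_dict())
    if not out:
        raise ValueError("no pixels fall inside any management unit")
    return pd.DataFrame(out)
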