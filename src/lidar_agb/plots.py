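"""Plot-level AGB density from tree-level records.

Tree tables carry one row per tree (or per recorded cluster of
similar-sized stems) with columns: species, dbh_cm, height_m (optional),
status ('live'|'dead'), agb_kg (per-tree AGB from an upstream allometry),
cluster_count (>= 1).  Plot AGB density sums live plus dead trees at or
above the 7.6 cm DBH inclusion threshold, converts kg to Mg, and divides
by the plot area in ha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DBH_MIN_CM", "expand_clusters", "aggregate_plot_agb",
           "placeholder_allometry", "read_tree_csv", "write_plot_csv"]

#: largest common minimum DBH across the contributing field protocols (cm);
#: the threshold is inclusive (trees at exactly 7.6 cm count).
DBH_MIN_CM = 7.6

TREE_COLUMNS = ["species", "dbh_cm", "height_m", "status", "agb_kg",
                "cluster_count"]


def _validate_trees(trees: pd.DataFrame) -> pd.DataFrame:
    trees = trees.copy()
    if "cluster_count" not in trees.columns:
        trees["cluster_count"] = 1
    if "height_m" not in trees.columns:
        trees["height_m"] = np.nan  # height is unused once agb_kg is supplied
    counts = trees["cluster_count"].to_numpy()
    if np.any(counts < 1) or np.any(counts != np.floor(counts)):
        raise ValueError("cluster_count must be a positive integer")
    if np.any(trees["dbh_cm"].to_numpy(dtype=float) <= 0):
        raise ValueError("dbh_cm must be > 0")
    if np.any(trees["agb_kg"].to_numpy(dtype=float) < 0):
        raise ValueError("agb_kg must be >= 0")
    return trees


def expand_clusters(trees: pd.DataFrame) -> pd.DataFrame:
    """Expand cluster records of k stems into k identical single-tree rows.

    Each member keeps the recorded (average) DBH, height and per-stem AGB;
    the total implied stem count and AGB are conserved.
    """
    trees = _validate_trees(trees)
    counts = trees["cluster_count"].to_numpy(dtype=int)
    out = trees.loc[trees.index.repeat(counts)].reset_index(drop=True)
    out["cluster_count"] = 1
    return out


def aggregate_plot_agb(trees: pd.DataFrame, area_ha: float,
                       dbh_min_cm: float = DBH_MIN_CM,
                       include_dead: bool = True) -> float:
    """Plot AGB density in Mg/ha.

    Sums agb_kg over live (and, by default, dead) trees with
    dbh_cm >= dbh_min_cm, converts kg to Mg, and divides by the plot area.
    Cluster records are expanded first, so passing an unexpanded table
    gives the same answer as expanding beforehand.  The live-only switch
    exists for comparisons against live-only map products.
    """
    if area_ha <= 0:
        raise ValueError("plot area must be > 0")
    trees = expand_clusters(trees)
    keep = trees["dbh_cm"].to_numpy(dtype=float) >= dbh_min_cm
    if not include_dead:
        keep &= trees["status"].astype(str).str.lower().to_numpy() == "live"
    total_kg = float(trees.loc[keep, "agb_kg"].sum())
    return total_kg / 1000.0 / area_ha


def placeholder_allometry(dbh_cm, a: float, b: float):
    """Power-law per-tree AGB, a * dbh^b (kg).

    A synthetic stand-in used only by the data generator; real analyses
    supply per-tree AGB from an external allometric pathway.
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    if a <= 0:
        raise ValueError("coefficient a must be > 0")
    if np.any(dbh <= 0):
        raise ValueError("dbh must be > 0")
    out = a * dbh ** b
    return float(out) if out.ndim == 0 else out


def read_tree_csv(path) -> pd.DataFrame:
    trees = pd.read_csv(path)
    missing = {"dbh_cm", "status", "agb_kg"} - set(trees.columns)
    if missing:
        raise ValueError(f"tree CSV missing columns: {sorted(missing)}")
    return _validate_trees(trees)


def write_plot_csv(plots: pd.DataFrame, path) -> None:
    cols = [c for c in ["plot_id", "x_km", "y_km", "area_ha", "agb_mg_ha",
                        "agb_sqrt", "dataset_tag", "year"] if c in plots.columns]
    plots[cols].to_csv(path, index=False)
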