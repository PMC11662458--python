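"""Gridded canopy-structure metrics from normalized point heights.

All coordinates in this module are meters (lidar convention); the modeling
layer works in km.  The 17 candidate metrics per 30 m cell are canopy
cover (percent of returns above the 2 m canopy threshold), mean and
standard deviation of above-threshold heights, 13 height percentiles
(5th-95th), and canopy rumple (triangulated canopy surface area over
planimetric area, computed from a fine canopy height model).

The 2 m threshold is strictly greater-than; percentiles use linear
interpolation between order statistics; the height-metric SD is the
population SD (ddof=0).  Cells whose returns are all at or below 2 m get
cover 0 with height metrics flagged undefined (NaN).  Cells with
physically implausible heights (95th percentile > 64 m or mean > 40 m, an
artifact signature of horizontal misregistration on cliffs) are masked and
excluded from all downstream use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box

__all__ = [
    "HEIGHT_THRESHOLD_M", "PERCENTILES", "P95_MASK_M", "MEAN_MASK_M",
    "MetricGrid", "compute_cell_metrics", "compute_rumple",
    "chm_from_points", "grid_from_points", "mask_height_artifacts",
    "extract_plot_metrics", "circle", "HEIGHT_METRICS",
]

HEIGHT_THRESHOLD_M = 2.0
PERCENTILES = (5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95)
P95_MASK_M = 64.0
MEAN_MASK_M = 40.0

_PCT_NAMES = [f"p{q:02d}" for q in PERCENTILES]
HEIGHT_METRICS = ["mean_height_m", "sd_height_m"] + _PCT_NAMES
CELL_METRICS = ["canopy_cover_pct"] + HEIGHT_METRICS
ALL_METRICS = ["canopy_cover_pct", "mean_height_m", "canopy_rumple",
               "sd_height_m"] + _PCT_NAMES


def compute_cell_metrics(heights) -> dict:
    """Cover and height metrics for the returns within one cell.

    Returns a dict over CELL_METRICS; height metrics are NaN when no return
    exceeds the canopy threshold.  Empty cells yield an all-NaN no-data
    record.
    """
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        return {k: np.nan for k in CELL_METRICS}
    above = h[h > HEIGHT_THRESHOLD_M]
    out = {"canopy_cover_pct": 100.0 * above.size / h.size}
    if above.size == 0:
        out.update({k: np.nan for k in HEIGHT_METRICS})
        return out
    out["mean_height_m"] = float(np.mean(above))
    out["sd_height_m"] = float(np.std(above))
    pct = np.percentile(above, PERCENTILES)  # linear interpolation
    out.update(dict(zip(_PCT_NAMES, pct)))
    return out


def compute_rumple(chm: np.ndarray, spacing: float = 1.0) -> float:
    """Ratio of triangulated canopy surface area to planimetric area (>= 1).

    Each grid square of the canopy height model is split into two triangles
    along a fixed NW-SE diagonal and the 3-D triangle areas are summed via
    the cross-product formula.
    """
    z = np.asarray(chm, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("CHM must have at least 2x2 nodes")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    dzdx_top = z[:-1, 1:] - z[:-1, :-1]
    dzdy_right = z[1:, 1:] - z[:-1, 1:]
    dzdy_left = z[1:, :-1] - z[:-1, :-1]
    dzdx_bot = z[1:, 1:] - z[1:, :-1]
    s = spacing
    # triangle (NW, NE, SE): normal cross((s,0,dzdx_top),(s,s,dz_diag)) etc.
    a1 = 0.5 * np.sqrt((s * dzdy_right) ** 2 + (s * dzdx_top) ** 2 + s ** 4)
    # triangle (NW, SW, SE)
    a2 = 0.5 * np.sqrt((s * dzdy_left) ** 2 + (s * dzdx_bot) ** 2 + s ** 4)
    plan = s ** 2 * (z.shape[0] - 1) * (z.shape[1] - 1)
    return float((a1.sum() + a2.sum()) / plan)


def chm_from_points(x, y, z, x0: float, y0: float, size_m: float,
                    res_m: float = 1.0) -> np.ndarray:
    """Canopy height model: highest return per fine cell; empty cells 0."""
    n = max(int(round(size_m / res_m)), 2)
    chm = np.zeros((n, n))
    ix = np.clip(((np.asarray(x) - x0) / res_m).astype(int), 0, n - 1)
    iy = np.clip(((np.asarray(y) - y0) / res_m).astype(int), 0, n - 1)
    np.maximum.at(chm, (iy, ix), np.asarray(z, dtype=float))
    return chm


@dataclass
class MetricGrid:
    """Regular metric raster with an artifact mask.

    data maps metric name -> (ny, nx) array; mask is True where a cell is
    excluded (height artifacts); n_points counts returns per cell.
    Row 0 is the southernmost row (y increases with row index).
    """

    x0_m: float
    y0_m: float
    cell_size_m: float
    data: dict = field(default_factory=dict)
    mask: np.ndarray | None = None
    n_points: np.ndarray | None = None

    @property
    def shape(self):
        return next(iter(self.data.values())).shape

    def cell_polygon(self, row: int, col: int):
        s = self.cell_size_m
        return box(self.x0_m + col * s, self.y0_m + row * s,
                   self.x0_m + (col + 1) * s, self.y0_m + (row + 1) * s)

    def to_frame(self) -> pd.DataFrame:
        ny, nx = self.shape
        rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        out = pd.DataFrame({"row": rows.ravel(), "col": cols.ravel()})
        for k, v in self.data.items():
            out[k] = v.ravel()
        out["mask"] = (self.mask.ravel() if self.mask is not None
                       else np.zeros(ny * nx, dtype=bool))
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, x0_m: float, y0_m: float,
                   cell_size_m: float) -> "MetricGrid":
        ny = int(frame["row"].max()) + 1
        nx = int(frame["col"].max()) + 1
        data = {}
        for k in frame.columns:
            if k in ("row", "col", "mask"):
                continue
            arr = np.full((ny, nx), np.nan)
            arr[frame["row"], frame["col"]] = frame[k].to_numpy(dtype=float)
            data[k] = arr
        mask = np.zeros((ny, nx), dtype=bool)
        if "mask" in frame.columns:
            mask[frame["row"], frame["col"]] = frame["mask"].to_numpy(dtype=bool)
        return cls(x0_m=x0_m, y0_m=y0_m, cell_size_m=cell_size_m,
                   data=data, mask=mask)


def grid_from_points(points: pd.DataFrame, x0_m: float, y0_m: float,
                     nx: int, ny: int, cell_size_m: float = 30.0,
                     chm_res_m: float = 1.0) -> MetricGrid:
    """Bin a normalized point cloud (columns x, y, z) onto a metric grid."""
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    z = points["z"].to_numpy(dtype=float)
    col = np.floor((x - x0_m) / cell_size_m).astype(int)
    row = np.floor((y - y0_m) / cell_size_m).astype(int)
    inside = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)

    data = {k: np.full((ny, nx), np.nan) for k in ALL_METRICS}
    npts = np.zeros((ny, nx), dtype=int)
    for r in range(ny):
        for c in range(nx):
            sel = inside & (row == r) & (col == c)
            npts[r, c] = int(sel.sum())
            if not npts[r, c]:
                continue
            cell = compute_cell_metrics(z[sel])
            for k, v in cell.items():
                data[k][r, c] = v
            chm = chm_from_points(x[sel], y[sel], z[sel],
                                  x0_m + c * cell_size_m,
                                  y0_m + r * cell_size_m,
                                  cell_size_m, chm_res_m)
            data["canopy_rumple"][r, c] = compute_rumple(chm, chm_res_m)
    grid = MetricGrid(x0_m=x0_m, y0_m=y0_m, cell_size_m=cell_size_m,
                      data=data, mask=np.zeros((ny, nx), dtype=bool),
                      n_points=npts)
    return mask_height_artifacts(grid)


def mask_height_artifacts(grid: MetricGrid, p95_max_m: float = P95_MASK_M,
                          mean_max_m: float = MEAN_MASK_M) -> MetricGrid:
    """Set the artifact mask where p95 > 64 m or mean height > 40 m."""
    p95 = grid.data["p95"]
    mean = grid.data["mean_height_m"]
    with np.errstate(invalid="ignore"):
        flag = (p95 > p95_max_m) | (mean > mean_max_m)
    grid.mask = np.where(np.isnan(p95) & np.isnan(mean), False, flag)
    return grid


def circle(cx: float, cy: float, radius_m: float):
    """Circular plot boundary (center + radius, meters)."""
    return Point(cx, cy).buffer(radius_m, quad_segs=128)


def extract_plot_metrics(geometry, grid: MetricGrid,
                         points: pd.DataFrame | None = None,
                         mode: str = "zonal") -> pd.Series:
    """Plot-level 17-metric vector from a grid (zonal) or point clip.

    zonal: area-weighted mean of the intersecting unmasked cells (NaN cell
    values are skipped per metric with weights renormalized).  point_clip:
    metrics recomputed from the points inside the plot boundary — except
    canopy rumple, which is always taken zonally because of its strong
    edge sensitivity.
    """
    if mode not in ("zonal", "point_clip"):
        raise ValueError("mode must be 'zonal' or 'point_clip'")
    geom = (circle(*geometry[1:]) if isinstance(geometry, tuple)
            and geometry[0] == "circle" else geometry)
    ny, nx = grid.shape
    s = grid.cell_size_m
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(int(np.floor((minx - grid.x0_m) / s)), 0)
    c1 = min(int(np.floor((maxx - grid.x0_m) / s)), nx - 1)
    r0 = max(int(np.floor((miny - grid.y0_m) / s)), 0)
    r1 = min(int(np.floor((maxy - grid.y0_m) / s)), ny - 1)
    cells, weights = [], []
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            if grid.mask is not None and grid.mask[r, c]:
                continue
            a = geom.intersection(grid.cell_polygon(r, c)).area
            if a > 0:
                cells.append((r, c))
                weights.append(a)
    if not cells:
        raise ValueError("plot does not overlap any unmasked grid cell")
    weights = np.asarray(weights)

    def zonal(name):
        vals = np.array([grid.data[name][r, c] for r, c in cells])
        ok = np.isfinite(vals)
        if not np.any(ok):
            return np.nan
        return float(np.average(vals[ok], weights=weights[ok]))

    if mode == "zonal":
        return pd.Series({k: zonal(k) for k in ALL_METRICS})

    if points is None:
        raise ValueError("point_clip mode requires the point cloud")
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    inside = shapely.contains_xy(geom, x, y)
    cell = compute_cell_metrics(points["z"].to_numpy(dtype=float)[inside])
    out = pd.Series({k: cell.get(k, np.nan) for k in ALL_METRICS})
    out["canopy_rumple"] = zonal("canopy_rumple")
    return out
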