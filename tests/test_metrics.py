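"""Canopy metric computation: cover/percentiles, rumple geometry, the
height-artifact mask, and plot-level extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lidar_agb.metrics import (MetricGrid, chm_from_points, circle,
                               compute_cell_metrics, compute_rumple,
                               extract_plot_metrics, grid_from_points,
                               mask_height_artifacts)
from lidar_agb.simulate import generate_point_cloud


class TestCellMetrics:
    def test_hand_counted_example(self):
        out = compute_cell_metrics([1.0, 1.0, 3.0, 5.0])
        assert out["canopy_cover_pct"] == pytest.approx(50.0)
        assert out["mean_height_m"] == pytest.approx(4.0)
        assert out["p50"] == pytest.approx(4.0)

    def test_constant_heights(self):
        out = compute_cell_metrics(np.full(20, 10.0))
        assert out["canopy_cover_pct"] == pytest.approx(100.0)
        assert out["sd_height_m"] == pytest.approx(0.0)
        assert all(out[f"p{q:02d}"] == pytest.approx(10.0)
                   for q in (5, 50, 95))

    def test_no_canopy_returns(self):
        out = compute_cell_metrics([0.5, 1.0, 2.0])  # 2.0 is not > 2
        assert out["canopy_cover_pct"] == pytest.approx(0.0)
        assert np.isnan(out["mean_height_m"]) and np.isnan(out["p95"])

    def test_empty_cell_is_nodata(self):
        out = compute_cell_metrics([])
        assert all(np.isnan(v) for v in out.values())

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 60.0), min_size=3, max_size=60))
    def test_reorder_and_understory_invariance(self, heights):
        base = compute_cell_metrics(heights)
        perm = compute_cell_metrics(heights[::-1])
        for k, v in base.items():
            np.testing.assert_allclose(perm[k], v, equal_nan=True)
        # adding below-threshold points lowers cover, leaves heights alone
        more = compute_cell_metrics(list(heights) + [0.2, 1.5])
        assert more["canopy_cover_pct"] <= base["canopy_cover_pct"] + 1e-12
        if np.isfinite(base["mean_height_m"]):
            assert more["mean_height_m"] == pytest.approx(base["mean_height_m"])
        # percentile vector is non-decreasing
        pct = [base[f"p{q:02d}"] for q in (5, 10, 20, 25, 30, 40, 50,
                                           60, 70, 75, 80, 90, 95)]
        if np.all(np.isfinite(pct)):
            assert np.all(np.diff(pct) >= -1e-12)


class TestRumple:
    def test_flat_chm_is_one(self):
        assert compute_rumple(np.full((5, 7), 13.0)) == pytest.approx(1.0)

    def test_single_raised_corner_analytic(self):
        # 2x2 CHM {0,0;0,h}: both triangles have area sqrt(1+h^2)/2
        h = 3.0
        chm = np.array([[0.0, 0.0], [0.0, h]])
        assert compute_rumple(chm, 1.0) == pytest.approx(np.sqrt(1 + h ** 2))

    def test_monotone_in_relief(self):
        rng = np.random.default_rng(3)
        chm = rng.uniform(0, 10, (8, 8))
        assert compute_rumple(2 * chm) > compute_rumple(chm) > 1.0

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            compute_rumple(np.array([[1.0, 2.0]]))


class TestArtifactMask:
    @pytest.mark.parametrize("mean, p95, masked", [
        (41.0, 50.0, True),   # mean-height rule
        (12.0, 65.0, True),   # p95 rule
        (12.0, 30.0, False),  # below both
        (40.0, 64.0, False),  # thresholds are strict
    ])
    def test_rules(self, mean, p95, masked):
        grid = MetricGrid(0, 0, 30.0, data={
            "mean_height_m": np.array([[mean]]),
            "p95": np.array([[p95]]),
        })
        assert mask_height_artifacts(grid).mask[0, 0] == masked


@pytest.fixture(scope="module")
def gridded():
    """Two adjacent 30 m cells: closed canopy west, open east."""
    dense = generate_point_cloud(100.0, 12.0, n_points=2000, seed=1)
    sparse = generate_point_cloud(0.0, None, n_points=2000, seed=2)
    sparse = sparse.assign(x=sparse["x"] + 30.0)
    points = pd.concat([dense, sparse], ignore_index=True)
    grid = grid_from_points(points, 0.0, 0.0, 2, 1)
    return grid, points


class TestExtraction:
    def test_single_cell_identity(self, gridded):
        grid, points = gridded
        from shapely.geometry import box
        vec = extract_plot_metrics(box(0, 0, 30, 30), grid)
        assert vec["canopy_cover_pct"] == pytest.approx(
            grid.data["canopy_cover_pct"][0, 0])
        assert vec["mean_height_m"] == pytest.approx(
            grid.data["mean_height_m"][0, 0])

    def test_equal_straddle_averages_cover(self, gridded):
        grid, _ = gridded
        from shapely.geometry import box
        vec = extract_plot_metrics(box(15, 0, 45, 30), grid)
        want = 0.5 * (grid.data["canopy_cover_pct"][0, 0]
                      + grid.data["canopy_cover_pct"][0, 1])
        assert vec["canopy_cover_pct"] == pytest.approx(want)

    def test_point_clip_recounts_cover(self, gridded):
        grid, points = gridded
        from shapely.geometry import box
        plot = box(2, 2, 28, 28)
        vec = extract_plot_metrics(plot, grid, points=points, mode="point_clip")
        inside = points[(points.x.between(2, 28)) & (points.y.between(2, 28))]
        want = 100.0 * (inside.z > 2).mean()
        assert vec["canopy_cover_pct"] == pytest.approx(want, abs=1e-9)
        # rumple stays zonal in point_clip mode
        zon = extract_plot_metrics(plot, grid, mode="zonal")
        assert vec["canopy_rumple"] == pytest.approx(zon["canopy_rumple"])

    def test_masked_cells_are_excluded(self, gridded):
        grid, _ = gridded
        grid2 = MetricGrid(grid.x0_m, grid.y0_m, grid.cell_size_m,
                           data=grid.data,
                           mask=np.ones_like(grid.mask))
        with pytest.raises(ValueError, match="unmasked"):
            extract_plot_metrics(circle(15, 15, 10), grid2)


class TestPointCloudGenerator:
    def test_prescribed_cover_and_height(self):
        pc = generate_point_cloud(100.0, 10.0, n_points=500, height_sd_m=0.0,
                                  seed=0)
        m = compute_cell_metrics(pc["z"])
        assert m["canopy_cover_pct"] == pytest.approx(100.0)
        assert m["mean_height_m"] == pytest.approx(10.0)

    def test_half_cover_recount(self):
        pc = generate_point_cloud(50.0, 8.0, n_points=1000, seed=3)
        m = compute_cell_metrics(pc["z"])
        assert m["canopy_cover_pct"] == pytest.approx(50.0, abs=0.2)

    def test_zero_cover(self):
        pc = generate_point_cloud(0.0, None, n_points=200, seed=4)
        assert (pc["z"] <= 2.0).all()

    def test_input_errors(self):
        with pytest.raises(ValueError):
            generate_point_cloud(50.0, 8.0, n_points=0)
        with pytest.raises(ValueError):
            generate_point_cloud(50.0, 1.0)


def test_chm_uses_highest_return():
    pts = pd.DataFrame({"x": [0.5, 0.5, 1.5], "y": [0.5, 0.5, 0.5],
                        "z": [3.0, 9.0, 4.0]})
    chm = chm_from_points(pts.x, pts.y, pts.z, 0.0, 0.0, 2.0, 1.0)
    assert chm[0, 0] == 9.0 and chm[0, 1] == 4.0
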