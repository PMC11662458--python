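"""Synthetic-data generator: random-field covariance (Monte Carlo vs
closed form), correlation calibration, determinism, and degenerate
noise-free limits."""

import numpy as np
import pandas as pd
import pytest

from lidar_agb.simulate import (METRIC_NAMES, SIGNAL_METRICS, SimulationConfig,
                                generate_pixel_grid, generate_plot_dataset,
                                generate_scene, simulate_gaussian_random_field)


class TestRandomField:
    def test_zero_variance_field(self):
        locs = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        np.testing.assert_array_equal(
            simulate_gaussian_random_field(locs, 0.0, 2.0, seed=1),
            np.zeros(3))

    def test_coincident_locations_identical(self):
        locs = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 0.0]])
        f = simulate_gaussian_random_field(locs, 3.0, 1.5, seed=2)
        assert f[0] == f[1]

    def test_monte_carlo_covariance(self):
        """Sample covariance over replicate draws converges to
        sigma2*exp(-phi*d) at several separations."""
        s2, phi = 4.0, 5.0
        dists = [0.2, 0.5, 1.0]
        locs = np.array([[0.0, 0.0]] + [[d, 0.0] for d in dists])
        rng = np.random.default_rng(0)
        draws = np.array([simulate_gaussian_random_field(locs, s2, phi, rng)
                          for _ in range(500)])
        C = np.cov(draws.T)
        for i, d in enumerate(dists, start=1):
            want = s2 * np.exp(-phi * d)
            assert C[0, i] == pytest.approx(want, abs=0.6)
        assert C[0, 0] == pytest.approx(s2, abs=0.8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            simulate_gaussian_random_field([[np.nan, 0.0]], 1.0, 1.0)
        with pytest.raises(ValueError):
            simulate_gaussian_random_field([[0.0, 0.0]], 1.0, 0.0)


class TestPlotDataset:
    def test_seed_determinism(self):
        a = generate_plot_dataset(SimulationConfig(n_plots=50, seed=5))
        b = generate_plot_dataset(SimulationConfig(n_plots=50, seed=5))
        pd.testing.assert_frame_equal(a.plots, b.plots)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        np.testing.assert_array_equal(a.true_w, b.true_w)

    def test_agb_is_square_of_response(self, default_dataset):
        p = default_dataset.plots
        np.testing.assert_allclose(p["agb_mg_ha"], p["agb_sqrt"] ** 2,
                                   rtol=1e-12)
        assert (p["agb_mg_ha"] >= 0).all()

    def test_metric_table_shape(self, default_dataset):
        assert len(default_dataset.metrics) == 360
        assert list(default_dataset.metrics.columns[1:]) == list(METRIC_NAMES)

    def test_calibrated_signal_correlations(self, default_dataset):
        """Signal metrics correlate with sqrt(AGB) at the calibration
        targets (0.74 / 0.84 / 0.85) within sampling tolerance."""
        y = default_dataset.plots["agb_sqrt"].to_numpy()
        targets = default_dataset.truth.target_correlations
        for nm, r in zip(SIGNAL_METRICS, targets):
            got = np.corrcoef(default_dataset.metrics[nm], y)[0, 1]
            assert got == pytest.approx(r, abs=0.05)

    def test_noise_free_limit_is_exact(self):
        cfg = SimulationConfig(n_plots=25, sigma2=0.0, tau2=0.0,
                               target_correlations=None, seed=8)
        ds = generate_plot_dataset(cfg)
        X = ds.metrics[list(SIGNAL_METRICS)].to_numpy()
        lin = cfg.beta[0] + X @ np.asarray(cfg.beta[1:])
        np.testing.assert_allclose(ds.plots["agb_mg_ha"], lin ** 2, rtol=1e-10)

    def test_unachievable_correlation_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(target_correlations=(0.74, 1.0, 0.85))
        with pytest.raises(ValueError):
            generate_plot_dataset(
                SimulationConfig(beta=(0.0, 1e-6, 1e-6, 1e-6),
                                 target_correlations=(0.9, 0.9, 0.9)))


class TestPixelGrid:
    def test_zero_variance_cells_identical(self):
        cfg = SimulationConfig(sigma2=0.0, tau2=0.0, latent_sigma2=0.0,
                               target_correlations=None, seed=1)
        grid = generate_pixel_grid(cfg, extent_km=((0.0, 0.06), (0.0, 0.06)),
                                   cell_size_m=30.0)
        t = grid.table
        assert len(t) == 4
        assert t["true_agb_mg_ha"].nunique() == 1
        assert t["canopy_cover_pct"].nunique() == 1

    def test_determinism(self):
        cfg = SimulationConfig(seed=4)
        a = generate_pixel_grid(cfg, extent_km=((0, 0.3), (0, 0.3)))
        b = generate_pixel_grid(cfg, extent_km=((0, 0.3), (0, 0.3)))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_mu_mean_is_arithmetic_mean(self):
        """Aggregating the true AGB surface (as a degenerate draw matrix)
        reproduces the direct per-unit average of its cells."""
        from lidar_agb.areal import mu_joint_estimate
        grid = generate_pixel_grid(SimulationConfig(seed=2),
                                   extent_km=((0, 1.5), (0, 1.5)))
        t = grid.table
        assert set(t["mu_id"].unique()) == {1, 2}
        draws = np.tile(t["true_agb_mg_ha"].to_numpy(), (120, 1))
        out = mu_joint_estimate(draws, t["mu_id"].to_numpy()).set_index("mu_id")
        for mu in (1, 2):
            direct = t.loc[t.mu_id == mu, "true_agb_mg_ha"].mean()
            assert out.loc[mu, "mean_mg_ha"] == pytest.approx(direct)

    def test_bad_cell_size(self):
        with pytest.raises(ValueError):
            generate_pixel_grid(SimulationConfig(), cell_size_m=0.0)
        with pytest.raises(ValueError):
            generate_pixel_grid(SimulationConfig(),
                                extent_km=((0, 0.03), (0, 0.03)))


class TestScene:
    def test_shared_realization(self):
        ds, grid = generate_scene(SimulationConfig(n_plots=40, seed=3),
                                  grid_shape=(6, 6))
        assert len(grid.table) == 36
        assert len(ds.plots) == 40
        # joint draw: rerunning reproduces both parts bit-for-bit
        ds2, grid2 = generate_scene(SimulationConfig(n_plots=40, seed=3),
                                    grid_shape=(6, 6))
        pd.testing.assert_frame_equal(ds.plots, ds2.plots)
        pd.testing.assert_frame_equal(grid.table, grid2.table)
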