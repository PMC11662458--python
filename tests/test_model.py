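"""Geostatistical core: covariance, likelihood (vs brute-force oracles),
the Gibbs conditional for beta (vs closed-form GLS), sampler determinism,
and posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg
from scipy.spatial.distance import pdist, squareform

from lidar_agb.model import (BiomassGeostatModel, EFF_RANGE_CONST, MCMCConfig,
                             Priors, effective_range, exp_covariance,
                             log_marginal_likelihood, nugget_to_sill,
                             summarize_posterior)
from lidar_agb.simulate import SIGNAL_METRICS, SimulationConfig, generate_plot_dataset
from tests.conftest import constant_samples


class TestCovariance:
    def test_zero_lag_is_sill(self):
        d = np.zeros((3, 3))
        np.testing.assert_allclose(exp_covariance(d, 2.5, 4.0),
                                   np.full((3, 3), 2.5))

    def test_effective_range_definition(self):
        phi = 3.0
        d = np.array([[0.0, EFF_RANGE_CONST / phi],
                      [EFF_RANGE_CONST / phi, 0.0]])
        C = exp_covariance(d, 2.0, phi)
        assert C[0, 1] == pytest.approx(0.05 * 2.0)

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10, (5, 2))
        C = exp_covariance(squareform(pdist(pts)), 3.0, 1.2)
        assert np.linalg.eigvalsh(C).min() >= -1e-10

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            exp_covariance(np.array([[-0.1]]), 1.0, 1.0)


def test_effective_range_values():
    assert effective_range(EFF_RANGE_CONST) == pytest.approx(1.0)
    assert effective_range(10 * EFF_RANGE_CONST) == pytest.approx(0.1)
    assert effective_range(5.0) > effective_range(6.0)
    with pytest.raises(ValueError):
        effective_range(0.0)


class TestMarginalLikelihood:
    def test_standard_normal_point(self):
        val = log_marginal_likelihood(
            np.array([0.0]), np.ones((1, 1)), np.array([0.0]),
            0.6, 0.4, 1.0, np.zeros((1, 1)))
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_matches_naive_dense_formula(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 5, (3, 2))
        D = squareform(pdist(pts))
        X = np.column_stack([np.ones(3), rng.standard_normal(3)])
        beta = np.array([1.0, -0.5])
        y = rng.standard_normal(3) + X @ beta
        s2, t2, phi = 2.0, 0.5, 1.5
        got = log_marginal_likelihood(y, X, beta, s2, t2, phi, D)
        Sigma = s2 * np.exp(-phi * D) + t2 * np.eye(3)
        r = y - X @ beta
        want = (-0.5 * (3 * np.log(2 * np.pi)
                        + np.log(np.linalg.det(Sigma))
                        + r @ np.linalg.inv(Sigma) @ r))
        assert got == pytest.approx(want, abs=1e-10)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 5, (4, 2))
        D = squareform(pdist(pts))
        X = np.ones((4, 1))
        y = rng.standard_normal(4)
        a = log_marginal_likelihood(y, X, np.array([0.0]), 1.0, 0.3, 2.0, D)
        b = log_marginal_likelihood(y + 7.0, X, np.array([7.0]), 1.0, 0.3, 2.0, D)
        assert a == pytest.approx(b, abs=1e-10)

    def test_matches_hierarchical_by_quadrature(self):
        """Marginalized likelihood equals the explicit-w likelihood
        integrated over w on a 2-plot toy (Gauss-Hermite)."""
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        X = np.ones((2, 1))
        beta = np.array([1.2])
        y = np.array([0.7, 2.1])
        s2, t2, phi = 1.5, 0.6, 2.0
        got = log_marginal_likelihood(y, X, beta, s2, t2, phi, D)

        R = s2 * np.exp(-phi * D)
        Lr = np.linalg.cholesky(R)
        nodes, wts = np.polynomial.hermite.hermgauss(60)
        total = 0.0
        for i, zi in enumerate(nodes):
            for j, zj in enumerate(nodes):
                w = Lr @ (np.sqrt(2.0) * np.array([zi, zj]))
                resid = y - X @ beta - w
                dens = np.exp(-0.5 * resid @ resid / t2) / (2 * np.pi * t2)
                total += wts[i] * wts[j] * dens
        want = np.log(total / np.pi)
        assert got == pytest.approx(want, abs=1e-6)


class TestNuggetToSill:
    def test_reported_null_model_medians(self):
        # tau2 0.83 against partial sill 22.48 -> extreme spatial dependence
        assert round(nugget_to_sill(0.83, 22.48), 2) == 0.04

    def test_limits(self):
        assert nugget_to_sill(0.0, 5.0) == 0.0
        assert nugget_to_sill(5.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            nugget_to_sill(0.0, 0.0)


class TestBetaConditional:
    def test_matches_closed_form_gls(self):
        """The Gibbs conditional for beta equals the (ridge-regularized)
        GLS posterior; checked by Monte Carlo against dense algebra."""
        rng = np.random.default_rng(8)
        ds = generate_plot_dataset(SimulationConfig(n_plots=30, seed=12))
        m = BiomassGeostatModel.from_dataframe(
            ds.plots, ds.metrics, metric_names=list(SIGNAL_METRICS))
        s2, t2, phi = 3.0, 0.8, 9.0
        L = m._sigma_factor(s2, t2, phi)
        draws = np.array([m._draw_beta(L, rng) for _ in range(40000)])

        Sigma = s2 * np.exp(-phi * m.dist_km) + t2 * np.eye(m.n)
        Si = np.linalg.inv(Sigma)
        V = np.linalg.inv(m.X.T @ Si @ m.X + np.eye(m.X.shape[1]) / m.priors.beta_var)
        mean = V @ m.X.T @ Si @ m.y
        se = np.sqrt(np.diag(V) / draws.shape[0])
        np.testing.assert_array_less(np.abs(draws.mean(0) - mean), 5 * se + 1e-12)
        np.testing.assert_allclose(np.cov(draws.T), V, rtol=0.08, atol=1e-4)


class TestSampler:
    def test_seed_determinism(self, small_dataset):
        m = BiomassGeostatModel.from_dataframe(
            small_dataset.plots, small_dataset.metrics,
            metric_names=list(SIGNAL_METRICS))
        a = m.fit(n_iter=400, n_burn=100, thin=3, seed=7)
        b = m.fit(n_iter=400, n_burn=100, thin=3, seed=7)
        np.testing.assert_array_equal(a.samples.beta, b.samples.beta)
        np.testing.assert_array_equal(a.samples.phi, b.samples.phi)

    def test_null_model_intercept_limit(self):
        """On near-constant data the null-model intercept posterior sits on
        the constant."""
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (40, 2))
        y = 6.0 + 0.05 * rng.standard_normal(40)
        m = BiomassGeostatModel(y, coords)
        res = m.fit(n_iter=1500, n_burn=500, thin=2, seed=1)
        med = res.posterior_median("beta_0")
        sd = res.samples.beta[:, 0].std()
        assert abs(med - 6.0) < 2 * sd + 0.05

    def test_duplicate_locations_jittered(self):
        coords = np.zeros((12, 2))
        coords[6:] = 1.0
        with pytest.warns(UserWarning, match="jittered"):
            m = BiomassGeostatModel(np.arange(12.0), coords)
        off = m.dist_km[np.triu_indices(12, k=1)]
        assert (off > 0).all()

    def test_covariates_absorb_spatial_variance(self):
        """Partial sill drops sharply from the null to the covariate model
        when the metrics carry the signal."""
        ds = generate_plot_dataset(SimulationConfig(n_plots=120, seed=21))
        null = BiomassGeostatModel.from_dataframe(ds.plots).fit(
            n_iter=2000, n_burn=800, thin=3, seed=2)
        cov = BiomassGeostatModel.from_dataframe(
            ds.plots, ds.metrics, metric_names=list(SIGNAL_METRICS)).fit(
            n_iter=2000, n_burn=800, thin=3, seed=2)
        s2_null = null.posterior_median("sigma2")
        s2_cov = cov.posterior_median("sigma2")
        assert s2_null > 3 * s2_cov
        # and the null model's nugget-to-sill indicates strong dependence
        assert null.nugget_to_sill() < 0.3


class TestSummaries:
    def test_constant_draws(self):
        s = constant_samples([1.0], 2.0, 0.5, 3.0, n_draws=150)
        table = summarize_posterior(s)
        row = table.loc["sigma2"]
        assert row["50%"] == row["2.5%"] == row["97.5%"] == pytest.approx(2.0)

    def test_normal_draw_quantiles(self):
        rng = np.random.default_rng(11)
        s = constant_samples([0.0], 1.0, 1.0, 1.0, n_draws=10000)
        s.beta = rng.standard_normal((10000, 1))
        table = summarize_posterior(s)
        row = table.loc["beta_0"]
        assert row["50%"] == pytest.approx(0.0, abs=0.05)
        assert row["2.5%"] == pytest.approx(-1.96, abs=0.08)
        assert row["97.5%"] == pytest.approx(1.96, abs=0.08)

    def test_effective_range_is_monotone_transform(self):
        rng = np.random.default_rng(4)
        s = constant_samples([0.0], 1.0, 1.0, 1.0, n_draws=501)
        s.phi = rng.uniform(1.0, 30.0, 501)
        table = summarize_posterior(s)
        assert table.loc["eff_range_km", "50%"] == pytest.approx(
            EFF_RANGE_CONST / np.median(s.phi))
        assert table.loc["eff_range_km", "2.5%"] == pytest.approx(
            EFF_RANGE_CONST / np.quantile(s.phi, 0.975), rel=1e-2)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(constant_samples([0.0], 1, 1, 1, n_draws=50))


def test_plotting_smoke(small_dataset):
    """Trace and map plots render without touching a display."""
    import matplotlib
    matplotlib.use("Agg")
    m = BiomassGeostatModel.from_dataframe(
        small_dataset.plots, small_dataset.metrics,
        metric_names=list(SIGNAL_METRICS))
    res = m.fit(n_iter=400, n_burn=150, thin=2, seed=0)
    axes = res.plot_trace()
    assert len(axes) == 3
    pred = res.predict(small_dataset.plots[["x_km", "y_km"]].to_numpy()[:10],
                       small_dataset.metrics.iloc[:10], seed=0)
    ax = pred.plot_map()
    assert ax is not None


def test_priors_validation():
    with pytest.raises(ValueError):
        Priors(phi_lo=2.0, phi_hi=1.0)
    with pytest.raises(ValueError):
        MCMCConfig(n_iter=100, n_burn=100)
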