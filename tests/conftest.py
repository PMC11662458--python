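import numpy as np
import pandas as pd
import pytest

from lidar_agb.model import PosteriorSamples
from lidar_agb.simulate import SIGNAL_METRICS, SimulationConfig, generate_plot_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic plot dataset shared by read-only tests."""
    return generate_plot_dataset(SimulationConfig(n_plots=120, seed=42))


@pytest.fixture(scope="session")
def default_dataset():
    """The default-condition dataset (n=360) shared by read-only tests."""
    return generate_plot_dataset(SimulationConfig(seed=0))


def constant_samples(beta, sigma2, tau2, phi, n_draws=200):
    """Posterior 'samples' holding every draw at fixed parameter values.

    Turns composition prediction into plain kriging with known theta, which
    closed-form oracles can check.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    T = n_draws
    return PosteriorSamples(
        beta=np.tile(beta, (T, 1)),
        sigma2=np.full(T, float(sigma2)),
        tau2=np.full(T, float(tau2)),
        phi=np.full(T, float(phi)),
        acceptance_rate=0.3,
        beta_names=[f"beta_{i}" for i in range(beta.size)],
    )


@pytest.fixture
def make_constant_samples():
    return constant_samples


@pytest.fixture
def tree_table():
    return pd.DataFrame({
        "species": ["PIAL", "PICO", "TSME"],
        "dbh_cm": [10.0, 30.0, 7.5],
        "height_m": [6.0, 18.0, 5.0],
        "status": ["live", "dead", "live"],
        "agb_kg": [300.0, 200.0, 50.0],
        "cluster_count": [1, 1, 1],
    })
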