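"""Shared fixtures: small simulated birds reused across test modules."""

import numpy as np
import pytest

from tandemtrack.ctmm_core import fit_ctmm, fit_family
from tandemtrack.synthetic_data import (
    SimulationConfig,
    observe_gps,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def gps_bird():
    """One migratory GPS-regime bird: (config, trajectory, observed series)."""
    cfg = SimulationConfig(seed=7)
    rng = np.random.default_rng(7)
    traj = simulate_trajectory(cfg, "bird7", rng=rng, migratory=True)
    series = observe_gps(traj, cfg, rng=rng)
    return cfg, traj, series


@pytest.fixture(scope="session")
def fitted_gps_bird(gps_bird):
    """The same bird with its selected movement model (full selection path)."""
    cfg, traj, series = gps_bird
    models = fit_ctmm(series, harmonic_grid=(0, 1, 2))
    return cfg, traj, series, models


@pytest.fixture(scope="session")
def resident_bird():
    """A non-migratory bird with a plain OUF fit at zero harmonics."""
    cfg = SimulationConfig(seed=11, duration=500 * 86400.0)
    rng = np.random.default_rng(11)
    traj = simulate_trajectory(cfg, "res11", rng=rng, migratory=False)
    series = observe_gps(traj, cfg, rng=rng)
    model = fit_family(series, "OUF", n_harmonics=0)
    return cfg, traj, series, model
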