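"""Shared fixtures: presets, reference runs, and a synthetic-trajectory builder.

The expensive simulations are session-scoped so that the observable and
acceptance tests share them.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import bfmsim as b
from bfmsim import engine


SWEEP_LOADS = [0.1, 0.3, 1.0, 3.0, 5.0, 10.0, 20.0, 50.0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_params() -> b.ModelParameters:
    return b.PRESETS["comparable_potentials"].params


@pytest.fixture(scope="session")
def tight_params() -> b.ModelParameters:
    return b.PRESETS["tight_coupling"].params


@pytest.fixture(scope="session")
def low_load_traj(default_params) -> engine.Trajectory:
    """Comparable potentials in the no-slip low-load regime."""
    return engine.run_simulation(default_params.replace(xi_R=0.1, t_total=10.0))


@pytest.fixture(scope="session")
def high_load_traj(default_params) -> engine.Trajectory:
    """Comparable potentials in the slipping high-load regime."""
    return engine.run_simulation(default_params.replace(xi_R=5.0, t_total=10.0))


@pytest.fixture(scope="session")
def tight_low_traj(tight_params) -> engine.Trajectory:
    """Tight coupling at low load; >= 50 completed power strokes."""
    return engine.run_simulation(tight_params.replace(xi_R=0.1, t_total=5.0))


@pytest.fixture(scope="session")
def load_sweep(default_params):
    """Load sweep of the comparable preset, 2 replicates per load."""
    return engine.run_load_sweep(
        default_params.replace(t_total=10.0), SWEEP_LOADS, replicates=2
    )


def make_trajectory(t, theta_S, theta_R, params, protons=None) -> engine.Trajectory:
    """Build a synthetic Trajectory directly from arrays (for observables tests)."""
    t = np.asarray(t, float)
    theta_S = np.asarray(theta_S, float)
    theta_R = np.asarray(theta_R, float)
    n = len(t)
    if protons is None:
        protons = np.zeros(n, dtype=np.int64)
    return engine.Trajectory(
        t=t,
        theta_S=theta_S,
        theta_R=theta_R,
        phi=theta_R - params.gear_ratio_k * theta_S,
        anchor_1=np.zeros(n, dtype=np.int64),
        anchor_2=np.zeros(n, dtype=np.int64),
        protons=np.asarray(protons),
        events=pd.DataFrame(
            {
                "time": np.empty(0),
                "motb_index": np.empty(0, dtype=np.int64),
                "theta_S": np.empty(0),
                "cumulative_protons": np.empty(0, dtype=np.int64),
            }
        ),
        params=params,
        seed=params.seed,
    )
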