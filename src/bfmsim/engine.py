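"""Langevin integration of the coupled stator/rotor rings.

Both rings obey overdamped Langevin equations:

.. math::

    \\xi_R \\dot\\theta_R &= -\\partial V_R/\\partial\\theta_R + \\eta_R(t), \\\\
    \\xi_S \\dot\\theta_S &= -\\partial V_R/\\partial\\theta_S
                            - \\partial V_S/\\partial\\theta_S + \\eta_S(t),

with independent white noises of covariance ``2*kBT*xi*delta(t-t')``.  The
equations are integrated with the Euler-Maruyama scheme; after each
mechanical update the chemical stepping rule is attempted (first-order
probability ``k_m*dt`` per MotB).  Angles are stored unwrapped.

For long runs the inner loop is delegated to a compiled kernel
(:mod:`bfmsim._kernel`); :func:`langevin_step` is the reference,
pure-Python single step over the public potentials/chemistry API and is
held bit-consistent with the kernel by the test suite.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemistry, potentials
from ._kernel import integrate_chunk
from .params import ModelParameters
from .chemistry import MotBUnit, StepEvent

__all__ = [
    "MotorState",
    "Trajectory",
    "initial_state",
    "langevin_step",
    "run_simulation",
    "run_load_sweep",
]

#: Steps per noise block; fixed so that trajectories are bit-reproducible
#: regardless of duration.
_CHUNK = 1_000_000

#: Columns of the trajectory CSV format.
TRAJECTORY_COLUMNS = ("t", "theta_S", "theta_R", "phi", "anchor_1", "anchor_2", "protons")


@dataclasses.dataclass(frozen=True)
class MotorState:
    """Instantaneous state: time, unwrapped ring angles, two MotB units."""

    t: float
    theta_S: float
    theta_R: float
    units: tuple[MotBUnit, MotBUnit]

    def phi(self, params: ModelParameters) -> float:
        """Scaled relative angle ``theta_R - k*theta_S``."""
        return self.theta_R - params.gear_ratio_k * self.theta_S


def initial_state(params: ModelParameters) -> MotorState:
    """Standard initial condition: ``theta_S = theta_R = 0``.

    MotB_1's well places the ring at the start of its plateau (P+ state);
    MotB_2 sits mid-cycle with the ring at the top of its ramp, so the
    motor starts under load from MotB_2 and the two units alternate from
    the first step on.
    """
    units = (
        MotBUnit(index=1, anchor=0, delta=0.0),
        MotBUnit(index=2, anchor=-1, delta=params.delta_theta_S / 2.0),
    )
    return MotorState(t=0.0, theta_S=0.0, theta_R=0.0, units=units)


def _step_py(state: MotorState, params: ModelParameters, gR, gS, u1, u2):
    """One Euler-Maruyama step with pre-drawn noise; returns (state, events)."""
    tau_R, tau_Sc, tau_Sm = potentials.torques(
        state.theta_S, state.theta_R, state.units, params
    )
    dt = params.dt
    th_R = state.theta_R + tau_R / params.xi_R * dt + math.sqrt(
        2.0 * params.kBT * dt / params.xi_R
    ) * gR
    th_S = state.theta_S + (tau_Sc + tau_Sm) / params.xi_S * dt + math.sqrt(
        2.0 * params.kBT * dt / params.xi_S
    ) * gS
    if not (math.isfinite(th_S) and math.isfinite(th_R)):
        raise RuntimeError(
            f"non-finite update from theta_S={state.theta_S!r}, "
            f"theta_R={state.theta_R!r} at dt={dt!r}; reduce dt"
        )
    moved = dataclasses.replace(state, t=state.t + dt, theta_S=th_S, theta_R=th_R)
    return chemistry._attempt_steps(moved, params, u1, u2, dt)


def langevin_step(state: MotorState, params: ModelParameters, rng) -> MotorState:
    """Advance the motor by one time step ``params.dt``.

    Draws two standard normals (rotor, stator) and two uniforms (one per
    MotB) from ``rng``, in that order.
    """
    z = rng.standard_normal(2)
    u = rng.random(2)
    new_state, _events = _step_py(
        state, params, float(z[0]), float(z[1]), float(u[0]), float(u[1])
    )
    return new_state


@dataclasses.dataclass
class Trajectory:
    """Uniformly sampled time series of a single motor run.

    Arrays are sampled every ``params.dt * params.sample_every`` time
    units, sample 0 being the initial state.  ``phi`` is the scaled
    relative angle ``theta_R - k*theta_S``; ``protons`` the cumulative
    proton count over both MotB units.  ``events`` lists every individual
    stepping event (columns: time, motb_index, theta_S,
    cumulative_protons).
    """

    t: np.ndarray
    theta_S: np.ndarray
    theta_R: np.ndarray
    phi: np.ndarray
    anchor_1: np.ndarray
    anchor_2: np.ndarray
    protons: np.ndarray
    events: pd.DataFrame
    params: ModelParameters
    seed: int

    def __len__(self) -> int:
        return len(self.t)

    @property
    def sample_dt(self) -> float:
        return self.params.dt * self.params.sample_every

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path, write_sidecars: bool = True) -> None:
        """Write the sampled series; optionally the config sidecar and
        the step-event table next to it (``<stem>.config.yaml`` and
        ``<stem>.events.csv``)."""
        path = Path(path)
        frame = pd.DataFrame(
            {
                "t": self.t,
                "theta_S": self.theta_S,
                "theta_R": self.theta_R,
                "phi": self.phi,
                "anchor_1": self.anchor_1,
                "anchor_2": self.anchor_2,
                "protons": self.protons,
            }
        )
        frame.to_csv(path, index=False)
        if write_sidecars:
            self.params.to_yaml(path.with_suffix(".config.yaml"))
            self.events.to_csv(path.with_suffix(".events.csv"), index=False)

    @classmethod
    def from_csv(cls, path, params: ModelParameters | None = None) -> "Trajectory":
        path = Path(path)
        frame = pd.read_csv(path)
        missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(
                f"trajectory file {path} is missing column(s): {', '.join(missing)}"
            )
        if params is None:
            sidecar = path.with_suffix(".config.yaml")
            if not sidecar.exists():
                raise ValueError(
                    f"no parameters given and no config sidecar at {sidecar}"
                )
            params = ModelParameters.from_yaml(sidecar)
        events_path = path.with_suffix(".events.csv")
        if events_path.exists():
            events = pd.read_csv(events_path)
        else:
            events = _empty_events()
        return cls(
            t=frame["t"].to_numpy(),
            theta_S=frame["theta_S"].to_numpy(),
            theta_R=frame["theta_R"].to_numpy(),
            phi=frame["phi"].to_numpy(),
            anchor_1=frame["anchor_1"].to_numpy(),
            anchor_2=frame["anchor_2"].to_numpy(),
            protons=frame["protons"].to_numpy(),
            events=events,
            params=params,
            seed=params.seed,
        )


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": np.empty(0),
            "motb_index": np.empty(0, dtype=np.int64),
            "theta_S": np.empty(0),
            "cumulative_protons": np.empty(0, dtype=np.int64),
        }
    )


def run_simulation(params: ModelParameters) -> Trajectory:
    """Simulate the motor for ``t_total`` and return the sampled trajectory.

    Identical ``(params, seed)`` pairs produce bit-identical trajectories.
    """
    state = initial_state(params)
    n_steps = params.n_steps
    if n_steps < 1:
        raise ValueError("t_total/dt must be at least one step")
    se = params.sample_every
    n_samples = n_steps // se + 1
    samp_thS = np.empty(n_samples)
    samp_thR = np.empty(n_samples)
    samp_n1 = np.empty(n_samples, dtype=np.int64)
    samp_n2 = np.empty(n_samples, dtype=np.int64)
    samp_thS[0] = state.theta_S
    samp_thR[0] = state.theta_R
    n1_0 = state.units[0].anchor
    n2_0 = state.units[1].anchor
    samp_n1[0] = n1_0
    samp_n2[0] = n2_0

    rng = np.random.default_rng(params.seed)
    th_S, th_R = state.theta_S, state.theta_R
    n1, n2 = n1_0, n2_0
    ev_times: list[np.ndarray] = []
    ev_idxs: list[np.ndarray] = []
    ev_thSs: list[np.ndarray] = []
    done = 0
    while done < n_steps:
        m = min(_CHUNK, n_steps - done)
        z = rng.standard_normal((m, 2))
        u = rng.random((m, 2))
        ev_t = np.empty(2 * m)
        ev_idx = np.empty(2 * m, dtype=np.int64)
        ev_thS = np.empty(2 * m)
        th_S, th_R, n1, n2, nev = integrate_chunk(
            th_S,
            th_R,
            n1,
            n2,
            done,
            m,
            params.delta_theta_S,
            params.delta_theta_R,
            params.gear_ratio_k,
            params.U_S,
            params.U_R,
            params.U_barrier,
            params.barrier_width,
            params.plateau_fraction,
            params.k0,
            params.window_width,
            params.xi_S,
            params.xi_R,
            params.kBT,
            params.dt,
            se,
            z,
            u,
            samp_thS,
            samp_thR,
            samp_n1,
            samp_n2,
            ev_t,
            ev_idx,
            ev_thS,
        )
        if nev:
            ev_times.append(ev_t[:nev].copy())
            ev_idxs.append(ev_idx[:nev].copy())
            ev_thSs.append(ev_thS[:nev].copy())
        done += m

    if ev_times:
        times = np.concatenate(ev_times)
        idxs = np.concatenate(ev_idxs)
        thSs = np.concatenate(ev_thSs)
        events = pd.DataFrame(
            {
                "time": times,
                "motb_index": idxs,
                "theta_S": thSs,
                "cumulative_protons": np.arange(1, len(times) + 1, dtype=np.int64),
            }
        )
    else:
        events = _empty_events()

    t = np.arange(n_samples) * (se * params.dt)
    protons = (samp_n1 - n1_0) + (samp_n2 - n2_0)
    return Trajectory(
        t=t,
        theta_S=samp_thS,
        theta_R=samp_thR,
        phi=samp_thR - params.gear_ratio_k * samp_thS,
        anchor_1=samp_n1,
        anchor_2=samp_n2,
        protons=protons,
        events=events,
        params=params,
        seed=params.seed,
    )


def run_load_sweep(
    params: ModelParameters, loads, replicates: int = 1
) -> list[tuple[float, list[Trajectory]]]:
    """Run ``replicates`` independent simulations at each rotor load.

    All parameters other than ``xi_R`` are held fixed.  Replicate ``j``
    uses seed ``params.seed + j`` (the same seed set at every load, i.e.
    common random numbers across the sweep); each trajectory records its
    own seed.
    """
    loads = list(loads)
    if not loads:
        raise ValueError("load list must not be empty")
    if any(not (x > 0.0) for x in loads):
        raise ValueError("all loads must be strictly positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    results: list[tuple[float, list[Trajectory]]] = []
    for xi in loads:
        trajs = [
            run_simulation(params.replace(xi_R=float(xi), seed=params.seed + j))
            for j in range(replicates)
        ]
        results.append((float(xi), trajs))
    return results
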