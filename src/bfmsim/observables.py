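"""Trajectory analyses: speeds, torque-speed curve, slippage, protons.

Conventions used throughout:

* Torque on the rotor is estimated from the steady-state Langevin balance
  ``torque = xi_R * <rotor speed>`` (the convention of bead-drag load
  experiments); the time-average of the coupling torque ``-dV_R/dtheta_R``
  is available as an independent cross-check.
* The scaled relative angle ``phi = theta_R - k*theta_S`` is analysed
  unwrapped and referenced to its initial value, so slippage -- the stator
  leaving the rotor behind -- registers as net drift to ``phi < 0``.
* An initial burn-in fraction of every trajectory is discarded to remove
  initialization transients.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import potentials
from .engine import Trajectory
from .params import ModelParameters

__all__ = [
    "TorqueSpeedPoint",
    "MotionSegment",
    "mean_speed",
    "torque_speed_curve",
    "is_downward_concave",
    "phi_distribution",
    "negative_phi_mass",
    "classify_motion",
    "motion_time_fractions",
    "proton_accounting",
    "ProtonAccounting",
    "mean_coupling_torque",
]


@dataclasses.dataclass(frozen=True)
class TorqueSpeedPoint:
    """One point of the torque-speed curve (model units)."""

    xi_R: float
    mean_speed_R: float
    sem_speed_R: float
    mean_speed_S: float
    sem_speed_S: float
    torque: float
    sem_torque: float


@dataclasses.dataclass(frozen=True)
class MotionSegment:
    """One coarse-graining window of a trajectory with its motion type.

    Type I: rotor follows the stator at the gear ratio (no slip).
    Type II: reduced net motion of both rings (biased random walk).
    Type III: stator advances while the rotor is essentially stalled.
    """

    t_start: float
    t_end: float
    d_theta_S: float
    d_theta_R: float
    motion_type: str


def _burn_slice(traj: Trajectory, burn_in_fraction: float) -> slice:
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    return slice(int(len(traj) * burn_in_fraction), len(traj))


def mean_speed(
    traj: Trajectory,
    which: str = "rotor",
    burn_in_fraction: float = 0.1,
    n_blocks: int = 10,
) -> tuple[float, float]:
    """Mean angular speed after burn-in, with a block-averaged SEM.

    The mean is the end-to-end slope ``(theta_end - theta_start) /
    (t_end - t_start)``; the SEM is the standard error of the slopes of
    ``n_blocks`` contiguous blocks.
    """
    if which not in ("rotor", "stator"):
        raise ValueError("which must be 'rotor' or 'stator'")
    sl = _burn_slice(traj, burn_in_fraction)
    th = (traj.theta_R if which == "rotor" else traj.theta_S)[sl]
    t = traj.t[sl]
    if len(t) < 2 * n_blocks:
        raise ValueError(
            f"need at least {n_blocks} blocks of >=2 samples after burn-in, "
            f"got {len(t)} samples"
        )
    mean = (th[-1] - th[0]) / (t[-1] - t[0])
    edges = np.linspace(0, len(t) - 1, n_blocks + 1).astype(int)
    slopes = (th[edges[1:]] - th[edges[:-1]]) / (t[edges[1:]] - t[edges[:-1]])
    sem = float(np.std(slopes, ddof=1) / math.sqrt(n_blocks))
    return float(mean), sem


def torque_speed_curve(
    sweep_results, burn_in_fraction: float = 0.1
) -> list[TorqueSpeedPoint]:
    """Build the torque-speed curve from :func:`bfmsim.engine.run_load_sweep` output.

    One point per load, averaged over replicates, with ``torque = xi_R *
    mean rotor speed``.  Points are returned sorted by rotor speed.
    """
    sweep_results = list(sweep_results)
    if len(sweep_results) < 3:
        raise ValueError("need at least 3 loads for a torque-speed curve")
    points = []
    for xi, trajs in sweep_results:
        vR, sR, vS, sS = [], [], [], []
        for traj in trajs:
            span_S = np.ptp(traj.theta_S)
            span_R = np.ptp(traj.theta_R)
            if span_S == 0.0 and span_R == 0.0:
                raise ValueError(
                    f"degenerate (zero-variance) trajectory at xi_R={xi}"
                )
            m, s = mean_speed(traj, "rotor", burn_in_fraction)
            vR.append(m)
            sR.append(s)
            m, s = mean_speed(traj, "stator", burn_in_fraction)
            vS.append(m)
            sS.append(s)
        n = len(vR)
        mean_vR = float(np.mean(vR))
        sem_vR = float(np.sqrt(np.sum(np.square(sR))) / n)
        mean_vS = float(np.mean(vS))
        sem_vS = float(np.sqrt(np.sum(np.square(sS))) / n)
        points.append(
            TorqueSpeedPoint(
                xi_R=xi,
                mean_speed_R=mean_vR,
                sem_speed_R=sem_vR,
                mean_speed_S=mean_vS,
                sem_speed_S=sem_vS,
                torque=xi * mean_vR,
                sem_torque=xi * sem_vR,
            )
        )
    return sorted(points, key=lambda p: p.mean_speed_R)


def is_downward_concave(points: list[TorqueSpeedPoint]) -> bool:
    """Concavity diagnostic for the torque-speed curve.

    True when every mid-speed torque lies above the chord joining the
    lowest- and highest-speed points -- the downward-concave shape
    characteristic of the motor (high, nearly constant torque up to
    intermediate speeds, then a rapid fall).

    Points carry Monte-Carlo error, and near the free-running end several
    loads share almost the same speed, so each comparison allows a
    2-standard-error slack built from the SEMs of the point and of the
    chord endpoints.  For exact points (zero SEM) the check is strict.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    pts = sorted(points, key=lambda p: p.mean_speed_R)
    lo, hi = pts[0], pts[-1]
    v0, tau0 = lo.mean_speed_R, lo.torque
    v1, tau1 = hi.mean_speed_R, hi.torque
    slope = (tau1 - tau0) / (v1 - v0)
    for p in pts[1:-1]:
        w1 = (p.mean_speed_R - v0) / (v1 - v0)
        w0 = 1.0 - w1
        chord = tau0 + slope * (p.mean_speed_R - v0)
        slack = 2.0 * (
            p.sem_torque
            + abs(slope) * p.sem_speed_R
            + abs(w0) * lo.sem_torque
            + abs(w1) * hi.sem_torque
            + abs(slope) * (abs(w0) * lo.sem_speed_R + abs(w1) * hi.sem_speed_R)
        )
        if p.torque + slack <= chord:
            return False
    return True


def phi_distribution(
    traj: Trajectory,
    n_bins: int = 80,
    burn_in_fraction: float = 0.1,
    phi_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of the relative angle ``phi``.

    ``phi`` is taken unwrapped and referenced to its initial value.  The
    default window spans the data and at least two rotor periods on either
    side of zero, so no-slip runs show a sharp mode at 0 while slipping
    runs accumulate mass at ``phi < 0``.  Returns ``(bin_edges,
    densities)`` with ``sum(densities) * binwidth == 1``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    phi0 = traj.phi[0]
    sl = _burn_slice(traj, burn_in_fraction)
    phi = traj.phi[sl] - phi0
    if phi_range is None:
        pad = 2.0 * traj.params.delta_theta_R
        phi_range = (min(float(phi.min()), -pad), max(float(phi.max()), pad))
    densities, edges = np.histogram(phi, bins=n_bins, range=phi_range, density=True)
    return edges, densities


def negative_phi_mass(
    traj: Trajectory,
    threshold: float | None = None,
    burn_in_fraction: float = 0.1,
) -> float:
    """Fraction of time spent at ``phi`` below ``threshold`` (default
    ``-delta_theta_R/2``, i.e. more than half a rotor period behind)."""
    if threshold is None:
        threshold = -traj.params.delta_theta_R / 2.0
    phi0 = traj.phi[0]
    sl = _burn_slice(traj, burn_in_fraction)
    phi = traj.phi[sl] - phi0
    return float(np.mean(phi < threshold))


def classify_motion(
    traj: Trajectory,
    window_duration: float | None = None,
    slip_threshold: float = 0.25,
    near_zero: float = 0.05,
    forward_min: float | None = None,
) -> list[MotionSegment]:
    """Partition a trajectory into windows and classify each as type I/II/III.

    Per window of duration ``window_duration`` (default: the mean duration
    of one power stroke, ``delta_theta_S / mean stator speed``), with
    displacements ``d_theta_S`` and ``d_theta_R``:

    * type I  if the stator advances (``d_theta_S > forward_min``) and the
      rotor follows at the gear ratio within ``slip_threshold`` relative
      tolerance;
    * type III if the stator advances but ``|d_theta_R| <= near_zero``;
    * type II otherwise.

    Defaults: ``slip_threshold=0.25``, ``near_zero=0.05`` rad per window,
    ``forward_min=delta_theta_S/4`` per window.
    """
    P = traj.params.delta_theta_S
    k = traj.params.gear_ratio_k
    if forward_min is None:
        forward_min = P / 4.0
    if window_duration is None:
        v_S = (traj.theta_S[-1] - traj.theta_S[0]) / (traj.t[-1] - traj.t[0])
        if v_S <= 0:
            raise ValueError(
                "cannot infer a power-stroke window from a non-advancing "
                "stator; pass window_duration explicitly"
            )
        window_duration = P / v_S
    dt_sample = float(traj.t[1] - traj.t[0])
    spw = int(round(window_duration / dt_sample))
    if spw < 20:
        raise ValueError(
            f"window_duration spans only {spw} samples; need >= 20 "
            "(increase window_duration or sample more densely)"
        )
    n_windows = (len(traj) - 1) // spw
    if n_windows < 1:
        raise ValueError("trajectory is shorter than one window")
    segments = []
    for w in range(n_windows):
        i0, i1 = w * spw, (w + 1) * spw
        dS = float(traj.theta_S[i1] - traj.theta_S[i0])
        dR = float(traj.theta_R[i1] - traj.theta_R[i0])
        if dS > forward_min and abs(dR - k * dS) <= slip_threshold * k * abs(dS):
            kind = "I"
        elif dS > forward_min and abs(dR) <= near_zero:
            kind = "III"
        else:
            kind = "II"
        segments.append(
            MotionSegment(
                t_start=float(traj.t[i0]),
                t_end=float(traj.t[i1]),
                d_theta_S=dS,
                d_theta_R=dR,
                motion_type=kind,
            )
        )
    return segments


def motion_time_fractions(segments: list[MotionSegment]) -> dict[str, float]:
    """Fraction of analysed time spent in each motion type."""
    total = sum(s.t_end - s.t_start for s in segments)
    out = {"I": 0.0, "II": 0.0, "III": 0.0}
    for s in segments:
        out[s.motion_type] += (s.t_end - s.t_start) / total
    return out


@dataclasses.dataclass(frozen=True)
class ProtonAccounting:
    protons_total: int
    protons_per_power_stroke: float
    protons_per_rotor_rev: float
    slip_fraction: float


def proton_accounting(traj: Trajectory) -> ProtonAccounting:
    """Proton bookkeeping and the slip fraction over a whole trajectory.

    ``protons_per_power_stroke`` divides the total proton count by the net
    stator rotation in units of the stator period (2 in the ideal cycle:
    one proton per MotB per half-stroke); ``protons_per_rotor_rev`` by the
    net rotor rotation in revolutions (52 under tight coupling);
    ``slip_fraction = 1 - d_theta_R / (k * d_theta_S)``, clamped to
    [0, 1].  Both ratios carry an O(1/N) boundary bias from the partial
    strokes at either end of a finite run.
    """
    dS = float(traj.theta_S[-1] - traj.theta_S[0])
    dR = float(traj.theta_R[-1] - traj.theta_R[0])
    protons_total = int(traj.protons[-1] - traj.protons[0])
    if dS <= 0.0:
        raise ValueError("zero or negative net stator rotation")
    if protons_total < 2:
        raise ValueError("no completed power stroke in this trajectory")
    P = traj.params.delta_theta_S
    k = traj.params.gear_ratio_k
    per_stroke = protons_total / (dS / P)
    per_rev = protons_total / (dR / (2.0 * math.pi)) if dR > 0.0 else math.inf
    slip = 1.0 - dR / (k * dS)
    slip = min(max(slip, 0.0), 1.0)
    return ProtonAccounting(protons_total, per_stroke, per_rev, slip)


def mean_coupling_torque(traj: Trajectory, burn_in_fraction: float = 0.1) -> float:
    """Time-average of the rotor torque ``-dV_R/dtheta_R`` along the samples.

    Independent estimator of the drag torque ``xi_R * <rotor speed>``; the
    two agree within Monte-Carlo error in steady state.
    """
    sl = _burn_slice(traj, burn_in_fraction)
    g = potentials.coupling_grad(traj.phi[sl], traj.params)
    return float(np.mean(-np.asarray(g)))
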