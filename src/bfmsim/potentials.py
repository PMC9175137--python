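"""Interaction potentials of the two-ring motor and their gradients.

Two potentials shape the dynamics:

* ``V_S(theta_S) = V_1 + V_2`` -- the MotA-MotB stator potential, the sum of
  two identical anchored single wells offset by half a stator period
  (``delta_theta_S/2 = 2*pi/10``), one per MotB monomer.  Each well is
  piecewise linear: a steep back-flow barrier, a flat plateau of height
  ``U_S``, and a linear power-stroke ramp descending to the minimum.
* ``V_R(phi)`` -- the MotA-FliG coupling potential, a periodic triangular
  wave in the scaled relative angle ``phi = theta_R - k*theta_S`` with
  period ``delta_theta_R`` and amplitude ``U_R``.

Wells are *anchored*, not periodic: each MotB's landscape is a single well
referenced to its anchor angle ``n_i*delta_theta_S + delta_i`` and confined
on both sides -- by the back-flow barrier behind the plateau and by an
equally steep wall rising past the minimum, so the ring waits at the
minimum until the chemical step re-anchors the well (at which point the
forward wall becomes the new back-flow barrier).  Periodicity of the
driven motor arises from chemistry advancing the anchors, not from the
potential itself.

Gradients at kink points of the piecewise-linear shapes use the one-sided
derivative from the left (the side the motor arrives from under forward
rotation), except at an exact minimum of ``V_R`` where the symmetric value
zero is returned.
"""
from __future__ import annotations

import math

import numpy as np

from .params import ModelParameters

__all__ = [
    "single_well",
    "single_well_grad",
    "stator_potential",
    "coupling_potential",
    "coupling_grad",
    "torques",
]


def _as_finite_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def _maybe_scalar(value: np.ndarray, template) -> float | np.ndarray:
    if np.ndim(template) == 0:
        return float(value)
    return value


def single_well(x, params: ModelParameters):
    """Energy of one anchored MotA-MotB well at relative angle ``x``.

    ``x`` is the MotA ring angle relative to this MotB's current anchor.
    The fundamental shape, in kBT:

    * ``x < 0``: back-flow barrier, rising leftward from ``U_S`` with slope
      ``U_barrier/barrier_width`` (continues indefinitely -- a reflecting
      wall).
    * ``0 <= x < plateau_fraction*delta_theta_S``: flat plateau at ``U_S``.
    * ``plateau <= x < delta_theta_S``: linear descent to the minimum
      (value 0 at ``x = delta_theta_S``, by convention).
    * ``x >= delta_theta_S``: confining wall rising with the barrier slope,
      so the ring waits near the minimum until a chemical step re-anchors
      the well (the wall then becomes the new back-flow barrier).
    """
    arr = _as_finite_array(x, "single_well angle")
    P = params.delta_theta_S
    rs = params.ramp_start
    v = np.where(
        arr < 0.0,
        params.U_S - arr * params.barrier_slope,
        np.where(
            arr < rs,
            params.U_S,
            np.where(
                arr < P,
                (P - arr) * params.ramp_slope,
                (arr - P) * params.barrier_slope,
            ),
        ),
    )
    return _maybe_scalar(v, x)


def single_well_grad(x, params: ModelParameters):
    """Left-sided derivative dU/dx of :func:`single_well`."""
    arr = _as_finite_array(x, "single_well angle")
    P = params.delta_theta_S
    rs = params.ramp_start
    g = np.where(
        arr <= 0.0,
        -params.barrier_slope,
        np.where(
            arr <= rs,
            0.0,
            np.where(arr <= P, -params.ramp_slope, params.barrier_slope),
        ),
    )
    return _maybe_scalar(g, x)


def _validate_units(units, params: ModelParameters):
    u1, u2 = units
    if not math.isclose(
        u2.delta - u1.delta, params.delta_theta_S / 2.0, rel_tol=0.0, abs_tol=1e-12
    ):
        raise ValueError(
            "MotB phase offsets must satisfy delta_2 - delta_1 == delta_theta_S/2"
        )
    return u1, u2


def _relative_angles(theta_S, units, params: ModelParameters):
    u1, u2 = _validate_units(units, params)
    P = params.delta_theta_S
    x1 = np.asarray(theta_S, dtype=float) - u1.anchor * P - u1.delta
    x2 = np.asarray(theta_S, dtype=float) - u2.anchor * P - u2.delta
    return x1, x2


def stator_potential(theta_S, units, params: ModelParameters):
    """Total MotA-MotB potential ``V_S = V_1 + V_2`` at stator angle ``theta_S``.

    ``units`` is the pair of MotB units carrying anchor indices and phase
    offsets (``delta_1 = 0``, ``delta_2 = delta_theta_S/2``).
    """
    x1, x2 = _relative_angles(theta_S, units, params)
    v = single_well(x1, params) + single_well(x2, params)
    return _maybe_scalar(np.asarray(v), theta_S)


def coupling_potential(phi, params: ModelParameters):
    """MotA-FliG coupling potential ``V_R(phi)``: a symmetric triangular wave.

    Periodic with period ``delta_theta_R``, minimum 0 at ``phi == 0`` (mod
    the period), maximum ``U_R`` half a period away.
    """
    arr = _as_finite_array(phi, "phi")
    PR = params.delta_theta_R
    w = arr - PR * np.floor(arr / PR)
    v = params.U_R * 2.0 * np.minimum(w, PR - w) / PR
    return _maybe_scalar(v, phi)


def coupling_grad(phi, params: ModelParameters):
    """Left-sided derivative ``dV_R/dphi``; 0 at an exact minimum."""
    arr = _as_finite_array(phi, "phi")
    PR = params.delta_theta_R
    s = 2.0 * params.U_R / PR
    w = arr - PR * np.floor(arr / PR)
    g = np.where(w == 0.0, 0.0, np.where(w <= PR / 2.0, s, -s))
    return _maybe_scalar(g, phi)


def torques(theta_S, theta_R, units, params: ModelParameters):
    """Torques acting on the two rings at the given state.

    Returns ``(tau_R, tau_S_coupling, tau_S_motb)`` in kBT/rad:

    * ``tau_R = -dV_R/dtheta_R``: torque on the rotor from the MotA-FliG
      contact.
    * ``tau_S_coupling = -dV_R/dtheta_S = +k * V_R'(phi)``: the reaction
      torque on the stator from the same contact; satisfies the gear
      identity ``tau_S_coupling == -k * tau_R`` exactly.
    * ``tau_S_motb = -dV_S/dtheta_S``: the proton-powered driving torque on
      the stator from the MotA-MotB wells.
    """
    k = params.gear_ratio_k
    phi = np.asarray(theta_R, dtype=float) - k * np.asarray(theta_S, dtype=float)
    g = coupling_grad(phi, params)
    x1, x2 = _relative_angles(theta_S, units, params)
    gm = single_well_grad(x1, params) + single_well_grad(x2, params)
    tau_R = -np.asarray(g)
    tau_S_coupling = k * np.asarray(g)
    tau_S_motb = -np.asarray(gm)
    if np.ndim(theta_S) == 0 and np.ndim(theta_R) == 0:
        return float(tau_R), float(tau_S_coupling), float(tau_S_motb)
    return tau_R, tau_S_coupling, tau_S_motb
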