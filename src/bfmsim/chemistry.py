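"""The proton discharge-recharge cycle as position-dependent stepping.

Each MotB monomer cycles through three protonated conformations as the MotA
ring sweeps its well: P+ (periplasm-facing, early plateau), I+
(intermediate), and C+ (cytoplasm-facing, near the well minimum).  The
discharge-recharge chain C+ -> C- -> P- -> P+ is collapsed into a single
effective rate ``k_m(theta_S)``: a top-hat that equals ``k0`` inside a
window of half-width ``window_width`` around the well minimum and is zero
elsewhere.  A firing advances that MotB's anchor by one stator period --
shifting its landscape forward and lifting the ring from the old minimum
onto the new plateau -- and translocates exactly one proton.  There are no
backward chemical steps.
"""
from __future__ import annotations

import dataclasses

from .params import ModelParameters

__all__ = [
    "MotBUnit",
    "StepEvent",
    "relative_angle",
    "stepping_rate",
    "chemical_label",
    "attempt_steps",
]


@dataclasses.dataclass(frozen=True)
class MotBUnit:
    """Chemical state of one MotB monomer.

    ``anchor`` counts completed steps; the current well is referenced to
    the angle ``anchor * delta_theta_S + delta``.  ``protons`` counts
    protons translocated by this monomer (one per step, so ``protons ==
    anchor - anchor(t=0)`` along any trajectory).
    """

    index: int  # 1 or 2
    anchor: int
    delta: float  # phase offset: 0 for MotB_1, delta_theta_S/2 for MotB_2
    protons: int = 0


@dataclasses.dataclass(frozen=True)
class StepEvent:
    """One proton-translocation (landscape-shift) event."""

    time: float
    motb_index: int
    theta_S: float


def relative_angle(theta_S: float, unit: MotBUnit, params: ModelParameters) -> float:
    """MotA ring angle relative to this MotB's current anchor."""
    return theta_S - unit.anchor * params.delta_theta_S - unit.delta


def stepping_rate(theta_S: float, unit: MotBUnit, params: ModelParameters) -> float:
    """Effective chain-reaction rate ``k_m`` at the current stator angle.

    Equals ``k0`` when the relative angle lies within ``window_width`` of
    the well minimum at ``delta_theta_S`` (both window edges inclusive);
    zero on the plateau and ramp.
    """
    x = relative_angle(theta_S, unit, params)
    P = params.delta_theta_S
    w = params.window_width
    return params.k0 if (P - w) <= x <= (P + w) else 0.0


def chemical_label(theta_S: float, unit: MotBUnit, params: ModelParameters) -> str:
    """Coarse conformational label of a protonated MotB: 'P+', 'I+', or 'C+'.

    P+ covers the first half of the plateau (and the barrier region just
    behind it), C+ the stepping window near the minimum, and I+ everything
    in between.  Over one completed power stroke each unit visits
    P+ -> I+ -> C+ and returns to P+ at the step.
    """
    x = relative_angle(theta_S, unit, params)
    if x < 0.5 * params.ramp_start:
        return "P+"
    if x < params.delta_theta_S - params.window_width:
        return "I+"
    return "C+"


def _attempt_steps(state, params: ModelParameters, u1: float, u2: float, dt: float):
    """Core stepping rule given two pre-drawn uniforms (one per MotB).

    Each unit fires independently with probability ``k_m * dt``.  Returns
    the (possibly) updated state and the list of :class:`StepEvent`.
    """
    units = list(state.units)
    events: list[StepEvent] = []
    for j, (unit, u) in enumerate(zip(units, (u1, u2))):
        rate = stepping_rate(state.theta_S, unit, params)
        if rate > 0.0 and u < rate * dt:
            units[j] = dataclasses.replace(
                unit, anchor=unit.anchor + 1, protons=unit.protons + 1
            )
            events.append(StepEvent(state.t, unit.index, state.theta_S))
    if events:
        state = dataclasses.replace(state, units=(units[0], units[1]))
    return state, events


def attempt_steps(state, params: ModelParameters, rng, dt: float | None = None):
    """Fire at most one step per MotB with probability ``k_m*dt`` each.

    ``state`` is a :class:`bfmsim.engine.MotorState`; both units are tried
    independently, so both may fire within the same ``dt``.  Returns
    ``(new_state, events)``.
    """
    dt = params.dt if dt is None else dt
    u = rng.random(2)
    return _attempt_steps(state, params, float(u[0]), float(u[1]), dt)
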