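"""Independent brute-force references used by the test suite.

These helpers deliberately avoid the code paths of :mod:`bfmsim.potentials`
and :mod:`bfmsim.engine`: potentials are re-stated from their defining
formulas and integrated by quadrature or by a tiny-step Euler scheme, so
agreement between simulator and oracle is evidence rather than tautology.
They run at test scale only and are not part of the user-facing CLI.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .params import ModelParameters

__all__ = [
    "GridDistribution",
    "boltzmann_reference",
    "deterministic_slide_reference",
]


@dataclasses.dataclass(frozen=True)
class GridDistribution:
    """Probability masses on a uniform grid of cell centers."""

    grid: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masses)
        if np.any(m < 0.0) or not math.isclose(float(m.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("masses must be non-negative and sum to 1")

    @property
    def cell_width(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def cdf(self, x) -> np.ndarray:
        """Piecewise-linear CDF (each cell's mass spread uniformly over it)."""
        edges = np.concatenate(
            [self.grid - self.cell_width / 2.0, [self.grid[-1] + self.cell_width / 2.0]]
        )
        cum = np.concatenate([[0.0], np.cumsum(self.masses)])
        return np.interp(x, edges, cum)

    def ks_distance(self, samples) -> float:
        """Kolmogorov-Smirnov distance between a sample and this reference."""
        return float(stats.kstest(np.asarray(samples), self.cdf).statistic)


def _triangle_wave(phi, amplitude: float, period: float):
    """Triangular coupling potential, re-stated independently: proportional
    to the distance to the nearest lattice point of the rotor period."""
    w = np.mod(np.asarray(phi, dtype=float) / period, 1.0)
    return amplitude * 2.0 * np.minimum(w, 1.0 - w)


def _well_energy_reference(x, params: ModelParameters):
    """One anchored MotA-MotB well, re-stated from its defining geometry
    (vectorized over ``x``)."""
    x = np.asarray(x, dtype=float)
    P = params.delta_theta_S
    rs = params.plateau_fraction * P
    bar = params.U_barrier / params.barrier_width
    return np.select(
        [x >= P, x >= rs, x >= 0.0],
        [
            (x - P) * bar,
            params.U_S * (P - x) / (P - rs),
            np.full_like(x, params.U_S),
        ],
        default=params.U_S + bar * (-x),
    )


def boltzmann_reference(
    params: ModelParameters,
    anchors: tuple[int, int] = (0, -1),
    grid_n: int = 512,
    potential=None,
    domain: tuple[float, float] | None = None,
) -> GridDistribution:
    """Equilibrium (``k0 = 0``) distribution of the wrapped relative angle.

    Computes the Boltzmann weight ``exp(-(V_S + V_R)/kBT)`` on a
    ``grid_n x grid_n`` grid of the accessible ``(theta_S, phi)`` well --
    the stator confined between the back-flow barrier and the forward wall
    of the frozen anchored wells, phi over one rotor period -- and
    marginalizes onto ``phi`` by midpoint quadrature.  Raises if the well
    is unbounded (no barrier).

    For convergence/closed-form checks a 1-D ``potential`` callable with an
    explicit bounded ``domain`` may be substituted; the weight is then
    computed on that 1-D grid directly.
    """
    if params.kBT <= 0.0:
        raise ValueError("Boltzmann reference requires kBT > 0")
    PR = params.delta_theta_R

    if potential is not None:
        if domain is None:
            raise ValueError("a bounded domain is required with a custom potential")
        lo, hi = domain
        if not (math.isfinite(lo) and math.isfinite(hi) and hi > lo):
            raise ValueError("domain must be a finite interval")
        h = (hi - lo) / grid_n
        centers = lo + (np.arange(grid_n) + 0.5) * h
        v = np.asarray(potential(centers), dtype=float)
        w = np.exp(-(v - v.min()) / params.kBT)
        return GridDistribution(grid=centers, masses=w / w.sum())

    if params.U_barrier <= 0.0:
        raise ValueError(
            "accessible well is unbounded without a back-flow barrier "
            "(U_barrier = 0); cannot normalize the Boltzmann weight"
        )
    P = params.delta_theta_S
    a1, a2 = anchors
    ref1 = a1 * P
    ref2 = a2 * P + P / 2.0
    # Confinement: each well bounds theta_S to [ref - pad, ref + P + pad];
    # the intersection, padded by where the barriers exceed ~40 kBT.
    pad = params.barrier_width * (
        40.0 * params.kBT / max(params.U_barrier, 1e-12) + 1.0
    )
    lo = max(ref1, ref2) - pad
    hi = min(ref1, ref2) + P + pad
    if hi <= lo:
        raise ValueError("frozen anchors leave no accessible stator region")
    if domain is not None:
        lo, hi = domain
    hs = (hi - lo) / grid_n
    theta = lo + (np.arange(grid_n) + 0.5) * hs
    hp = PR / grid_n
    phi = (np.arange(grid_n) + 0.5) * hp
    v_s = _well_energy_reference(theta - ref1, params) + _well_energy_reference(
        theta - ref2, params
    )
    v_r = _triangle_wave(phi, params.U_R, PR)
    # separable total energy V_S(theta) + V_R(phi) on the 2-D grid
    v = v_s[:, None] + v_r[None, :]
    w = np.exp(-(v - v.min()) / params.kBT)
    masses = w.sum(axis=0)
    return GridDistribution(grid=phi, masses=masses / masses.sum())


def deterministic_slide_reference(
    initial_angle: float,
    params: ModelParameters,
    t_final: float,
    anchors: tuple[int, int] = (0, -1),
    dt: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless overdamped slide of the stator down ``V_S``, tiny-step Euler.

    Integrates ``xi_S * dtheta/dt = -dV_S/dtheta`` (the zero-temperature,
    frozen-chemistry limit with the rotor decoupled) at ``dt`` defaulting
    to 1/100 of the production step, using a central finite difference of
    the independently coded ``V_S``.  Returns ``(times, angles)`` including
    the initial point.
    """
    dt = params.dt / 100.0 if dt is None else dt
    n = int(round(t_final / dt))
    a1, a2 = anchors
    P = params.delta_theta_S
    h = 1e-7

    def v_total(theta: float) -> float:
        return float(
            _well_energy_reference(theta - a1 * P, params)
            + _well_energy_reference(theta - a2 * P - P / 2.0, params)
        )

    times = np.arange(n + 1) * dt
    angles = np.empty(n + 1)
    theta = float(initial_angle)
    angles[0] = theta
    for i in range(n):
        force = -(v_total(theta + h) - v_total(theta - h)) / (2.0 * h)
        theta += force / params.xi_S * dt
        angles[i + 1] = theta
    return times, angles
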