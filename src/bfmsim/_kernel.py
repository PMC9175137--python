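"""Compiled Euler-Maruyama inner loop.

The loop mirrors the reference single-step path (`engine._step_py`) exactly:
mechanical update of both angles first, then the chemical stepping attempt,
consuming two standard normals and two uniforms per step in a fixed order.
A consistency test in the suite ties the two implementations together.
"""
from __future__ import annotations

import math

import numba
import numpy as np


@numba.njit(cache=True)
def integrate_chunk(
    th_S: float,
    th_R: float,
    n1: int,
    n2: int,
    step_offset: int,
    m: int,
    P_S: float,
    P_R: float,
    gk: float,
    U_S: float,
    U_R: float,
    U_b: float,
    bw: float,
    pf: float,
    k0: float,
    ww: float,
    xi_S: float,
    xi_R: float,
    kBT: float,
    dt: float,
    sample_every: int,
    z: np.ndarray,  # (m, 2) standard normals: column 0 rotor, column 1 stator
    u: np.ndarray,  # (m, 2) uniforms: column 0 MotB_1, column 1 MotB_2
    samp_thS: np.ndarray,
    samp_thR: np.ndarray,
    samp_n1: np.ndarray,
    samp_n2: np.ndarray,
    ev_t: np.ndarray,
    ev_idx: np.ndarray,
    ev_thS: np.ndarray,
):
    ramp_start = pf * P_S
    ramp_slope = U_S / (P_S - ramp_start)
    bar_slope = U_b / bw
    vr_slope = 2.0 * U_R / P_R
    half_R = 0.5 * P_R
    aS = dt / xi_S
    aR = dt / xi_R
    nS = math.sqrt(2.0 * kBT * dt / xi_S)
    nR = math.sqrt(2.0 * kBT * dt / xi_R)
    p_step = k0 * dt
    lo = P_S - ww
    hi = P_S + ww
    half_delta = 0.5 * P_S
    nev = 0
    for i in range(m):
        # -- coupling torque (left-derivative; zero at the exact minimum)
        phi = th_R - gk * th_S
        w = phi - P_R * math.floor(phi / P_R)
        if w == 0.0:
            vr = 0.0
        elif w <= half_R:
            vr = vr_slope
        else:
            vr = -vr_slope
        # -- MotA-MotB driving torque, sum over the two anchored wells
        f = 0.0
        x1 = th_S - n1 * P_S
        if x1 <= 0.0:
            f += bar_slope
        elif x1 <= ramp_start:
            pass
        elif x1 <= P_S:
            f += ramp_slope
        else:
            f -= bar_slope
        x2 = th_S - n2 * P_S - half_delta
        if x2 <= 0.0:
            f += bar_slope
        elif x2 <= ramp_start:
            pass
        elif x2 <= P_S:
            f += ramp_slope
        else:
            f -= bar_slope
        # -- Euler-Maruyama update (rotor then stator, independent noise)
        th_R = th_R + aR * (-vr) + nR * z[i, 0]
        th_S = th_S + aS * (gk * vr + f) + nS * z[i, 1]
        if not (math.isfinite(th_S) and math.isfinite(th_R)):
            raise RuntimeError(
                "non-finite angle during integration (torque blow-up); reduce dt"
            )
        # -- chemistry after the mechanical update
        g = step_offset + i + 1
        x1 = th_S - n1 * P_S
        if lo <= x1 <= hi and u[i, 0] < p_step:
            ev_t[nev] = g * dt
            ev_idx[nev] = 1
            ev_thS[nev] = th_S
            nev += 1
            n1 += 1
        x2 = th_S - n2 * P_S - half_delta
        if lo <= x2 <= hi and u[i, 1] < p_step:
            ev_t[nev] = g * dt
            ev_idx[nev] = 2
            ev_thS[nev] = th_S
            nev += 1
            n2 += 1
        if g % sample_every == 0:
            j = g // sample_every
            samp_thS[j] = th_S
            samp_thR[j] = th_R
            samp_n1[j] = n1
            samp_n2[j] = n2
    return th_S, th_R, n1, n2, nev
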