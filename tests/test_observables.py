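"""Observable computations on synthetic and simulated trajectories."""
from __future__ import annotations

import numpy as np
import pytest

import bfmsim as b
from bfmsim import observables as obs
from bfmsim.observables import TorqueSpeedPoint
from bfmsim.params import ModelParameters, ROTOR_PERIOD, STATOR_PERIOD

from conftest import make_trajectory

P = STATOR_PERIOD
PR = ROTOR_PERIOD
K = 5 / 26


@pytest.fixture(scope="module")
def params():
    return ModelParameters()


class TestMeanSpeed:
    def test_linear_trajectory_exact(self, params):
        t = np.linspace(0, 10, 500)
        traj = make_trajectory(t, 3.0 * t, K * 3.0 * t, params)
        mean, sem = obs.mean_speed(traj, "stator", burn_in_fraction=0.0)
        assert mean == pytest.approx(3.0)
        assert sem == pytest.approx(0.0, abs=1e-12)

    def test_pure_noise_mean_consistent_with_zero(self, params, rng):
        t = np.linspace(0, 10, 2000)
        noise = np.cumsum(rng.normal(0, 0.05, size=len(t)))
        traj = make_trajectory(t, noise, noise, params)
        mean, sem = obs.mean_speed(traj, "stator", burn_in_fraction=0.0)
        assert abs(mean) < 3 * sem

    def test_too_few_blocks_raises(self, params):
        t = np.linspace(0, 1, 15)
        traj = make_trajectory(t, t, t, params)
        with pytest.raises(ValueError, match="blocks"):
            obs.mean_speed(traj, "rotor", burn_in_fraction=0.0)


class TestTorqueSpeedCurve:
    def _synthetic_sweep(self, params, slopes_by_load):
        t = np.linspace(0, 10, 400)
        return [
            (xi, [make_trajectory(t, 5 * s * t / K, s * t, params)])
            for xi, s in slopes_by_load
        ]

    def test_known_slopes_give_exact_torques(self, params):
        sweep = self._synthetic_sweep(params, [(1.0, 4.0), (2.0, 2.0), (4.0, 1.0)])
        points = obs.torque_speed_curve(sweep, burn_in_fraction=0.0)
        got = {p.xi_R: p.torque for p in points}
        assert got[1.0] == pytest.approx(4.0)
        assert got[2.0] == pytest.approx(4.0)
        assert got[4.0] == pytest.approx(4.0)
        assert [p.mean_speed_R for p in points] == sorted(
            p.mean_speed_R for p in points
        )

    def test_needs_three_loads(self, params):
        sweep = self._synthetic_sweep(params, [(1.0, 1.0), (2.0, 0.5)])
        with pytest.raises(ValueError, match="3 loads"):
            obs.torque_speed_curve(sweep)

    def test_degenerate_trajectory_raises(self, params):
        t = np.linspace(0, 10, 400)
        sweep = [(xi, [make_trajectory(t, 0 * t, 0 * t, params)]) for xi in (1, 2, 3)]
        with pytest.raises(ValueError, match="degenerate"):
            obs.torque_speed_curve(sweep, burn_in_fraction=0.0)

    def test_concavity_diagnostic(self):
        def pt(v, tau):
            return TorqueSpeedPoint(1.0, v, 0.0, 5 * v, 0.0, tau, 0.0)

        concave = [pt(0.0, 10.0), pt(5.0, 9.5), pt(9.0, 6.0), pt(10.0, 0.0)]
        convex = [pt(0.0, 10.0), pt(5.0, 2.0), pt(9.0, 0.5), pt(10.0, 0.0)]
        assert obs.is_downward_concave(concave)
        assert not obs.is_downward_concave(convex)


class TestPhiDistribution:
    def test_no_slip_all_mass_at_zero(self, params):
        t = np.linspace(0, 10, 1000)
        theta_S = 3.0 * t
        traj = make_trajectory(t, theta_S, K * theta_S, params)  # phi identically 0
        edges, dens = obs.phi_distribution(traj, n_bins=40, burn_in_fraction=0.0)
        widths = np.diff(edges)
        assert np.sum(dens * widths) == pytest.approx(1.0)
        occupied = np.nonzero(dens)[0]
        assert len(occupied) == 1
        assert edges[occupied[0]] <= 0.0 <= edges[occupied[0] + 1]

    def test_invalid_bins(self, params):
        t = np.linspace(0, 10, 100)
        traj = make_trajectory(t, t, K * t, params)
        with pytest.raises(ValueError):
            obs.phi_distribution(traj, n_bins=1)

    def test_slipping_mass_increases_with_load(self, low_load_traj, high_load_traj):
        """More phi-mass below -delta_theta_R/2 at high load (slippage)."""
        low = obs.negative_phi_mass(low_load_traj)
        high = obs.negative_phi_mass(high_load_traj)
        assert high > low

    def test_low_load_mode_at_zero(self, low_load_traj):
        """Low load: the phi distribution is concentrated around 0."""
        edges, dens = obs.phi_distribution(low_load_traj, n_bins=80)
        mode = np.argmax(dens)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert abs(centers[mode]) < PR / 2


class TestClassifyMotion:
    def test_no_slip_all_type_I(self, params):
        t = np.linspace(0, 10, 1001)
        traj = make_trajectory(t, 50 * t, K * 50 * t, params)
        segments = obs.classify_motion(traj, window_duration=0.5)
        assert len(segments) == 20
        assert all(s.motion_type == "I" for s in segments)

    def test_stalled_rotor_all_type_III(self, params):
        t = np.linspace(0, 10, 1001)
        traj = make_trajectory(t, 50 * t, np.zeros_like(t), params)
        segments = obs.classify_motion(traj, window_duration=0.5)
        assert all(s.motion_type == "III" for s in segments)

    def test_stalled_everything_type_II(self, params):
        t = np.linspace(0, 10, 1001)
        traj = make_trajectory(t, np.zeros_like(t) + 0.001 * t, 0.0 * t, params)
        segments = obs.classify_motion(traj, window_duration=0.5)
        assert all(s.motion_type == "II" for s in segments)

    def test_segments_tile_without_overlap(self, low_load_traj):
        segments = obs.classify_motion(low_load_traj)
        for a, bseg in zip(segments, segments[1:]):
            assert bseg.t_start == pytest.approx(a.t_end)
        fractions = obs.motion_time_fractions(segments)
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_window_too_small_raises(self, params):
        t = np.linspace(0, 10, 101)
        traj = make_trajectory(t, t, K * t, params)
        with pytest.raises(ValueError, match="need >= 20"):
            obs.classify_motion(traj, window_duration=0.5)

    def test_slipping_fraction_grows_with_load(self, low_load_traj, high_load_traj):
        """Time in type II+III movements is larger at high load."""
        low_segments = obs.classify_motion(low_load_traj)
        # use the same physical window for the high-load trajectory
        window = low_segments[0].t_end - low_segments[0].t_start
        high_segments = obs.classify_motion(high_load_traj, window_duration=window)
        f_low = obs.motion_time_fractions(low_segments)
        f_high = obs.motion_time_fractions(high_segments)
        assert f_high["II"] + f_high["III"] > f_low["II"] + f_low["III"]


class TestProtonAccounting:
    def test_no_slip_synthetic_zero_slip(self, params):
        t = np.linspace(0, 10, 500)
        protons = np.round(2 * 50 * t / P).astype(np.int64)
        traj = make_trajectory(t, 50 * t, K * 50 * t, params, protons=protons)
        acc = obs.proton_accounting(traj)
        assert acc.slip_fraction == 0.0
        assert acc.protons_per_power_stroke == pytest.approx(2.0, rel=0.01)

    def test_zero_rotation_raises(self, params):
        t = np.linspace(0, 10, 500)
        traj = make_trajectory(t, np.zeros_like(t), np.zeros_like(t), params)
        with pytest.raises(ValueError):
            obs.proton_accounting(traj)

    def test_tight_coupling_protons_per_rotor_rev(self, tight_low_traj):
        """26 rotor periods x 2 protons: 52 protons per rotor revolution."""
        acc = obs.proton_accounting(tight_low_traj)
        assert acc.protons_per_rotor_rev == pytest.approx(52.0, rel=0.02)
        assert acc.slip_fraction < 0.01

    def test_slip_fraction_monotone_in_load(self, load_sweep):
        slips = []
        for xi, trajs in load_sweep:
            slips.append(np.mean([obs.proton_accounting(t).slip_fraction for t in trajs]))
        assert all(b2 >= a - 0.01 for a, b2 in zip(slips, slips[1:]))


class TestTorqueEstimatorsAgree:
    def test_drag_torque_matches_coupling_average(self, high_load_traj):
        """xi_R * <rotor speed> equals the time-averaged coupling torque."""
        v, sem = obs.mean_speed(high_load_traj, "rotor")
        drag = high_load_traj.params.xi_R * v
        coupling = obs.mean_coupling_torque(high_load_traj)
        assert abs(drag - coupling) < max(
            2 * high_load_traj.params.xi_R * sem, 0.05 * abs(drag)
        )
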