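"""Optional static figures mirroring the standard analyses.

Matplotlib is imported lazily so that headless library use never touches a
plotting backend.
"""
from __future__ import annotations

from pathlib import Path

from . import observables


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_time_series(traj, path) -> None:
    """Rotor (solid) and stator (dashed) angles versus time."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(traj.t, traj.theta_R, "-", label=r"$\theta_R$")
    ax.plot(traj.t, traj.theta_S, "--", label=r"$\theta_S$")
    ax.set_xlabel("time")
    ax.set_ylabel("angle (rad)")
    ax.set_title(f"$\\xi_R$ = {traj.params.xi_R:g}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_theta_plane(traj, path) -> None:
    """Trajectory in the (theta_S, theta_R) plane with the no-slip guide line."""
    plt = _mpl()
    k = traj.params.gear_ratio_k
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    ax.plot(traj.theta_S, traj.theta_R, lw=0.8)
    ax.plot(
        traj.theta_S,
        k * traj.theta_S,
        "k--",
        lw=1.0,
        label=r"$\theta_R = k\,\theta_S$",
    )
    ax.set_xlabel(r"$\theta_S$ (rad)")
    ax.set_ylabel(r"$\theta_R$ (rad)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phi_hist(traj, path, n_bins=80, burn_in_fraction=0.1) -> None:
    plt = _mpl()
    edges, dens = observables.phi_distribution(
        traj, n_bins=n_bins, burn_in_fraction=burn_in_fraction
    )
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.stairs(dens, edges, fill=True, alpha=0.6)
    ax.set_xlabel(r"$\varphi = \theta_R - k\theta_S$ (rad)")
    ax.set_ylabel("probability density")
    ax.set_title(f"$\\xi_R$ = {traj.params.xi_R:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_torque_speed(points, path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    v = [p.mean_speed_R for p in points]
    tau = [p.torque for p in points]
    err = [p.sem_torque for p in points]
    ax.errorbar(v, tau, yerr=err, fmt="o-")
    ax.set_xlabel("rotor speed (rad/time)")
    ax.set_ylabel(r"torque $\xi_R\langle\dot\theta_R\rangle$ ($k_BT$/rad)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def figure_suite(trajs, out_dir, burn_in_fraction=0.1, n_bins=80) -> None:
    """Write the standard figure set for a list of trajectories."""
    out = Path(out_dir)
    for i, traj in enumerate(trajs):
        tag = f"xiR{traj.params.xi_R:g}_{i}"
        plot_time_series(traj, out / f"timeseries_{tag}.png")
        plot_theta_plane(traj, out / f"plane_{tag}.png")
        plot_phi_hist(
            traj,
            out / f"phi_hist_{tag}.png",
            n_bins=n_bins,
            burn_in_fraction=burn_in_fraction,
        )
    if len(trajs) >= 3:
        points = observables.torque_speed_curve(
            [(t.params.xi_R, [t]) for t in trajs], burn_in_fraction=burn_in_fraction
        )
        plot_torque_speed(points, out / "torque_speed.png")
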