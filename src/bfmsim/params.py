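"""Model parameters, presets, and flat-file configuration handling.

The model is nondimensionalized: energies are in units of :math:`k_BT`
(thermal energy at the reference temperature), angles in radians, and time
in an arbitrary unit :math:`\\tau` fixed by the rates.  Rotational drag
coefficients therefore carry units of :math:`k_BT\\,\\tau/\\mathrm{rad}^2`.

The ring geometry is fixed by stoichiometry: the MotA pentamer ring has
period :math:`\\Delta\\theta_S = 2\\pi/5` and the 26-subunit FliG ring has
period :math:`\\Delta\\theta_R = 2\\pi/26`, giving the gear ratio
:math:`k = \\Delta\\theta_R/\\Delta\\theta_S = 5/26`.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import yaml

__all__ = [
    "STATOR_PERIOD",
    "ROTOR_PERIOD",
    "GEAR_RATIO",
    "ModelParameters",
    "PRESETS",
    "Preset",
    "load_config",
]

TWO_PI = 2.0 * math.pi

#: Angular period of the MotA pentamer ring (5 subunits), rad.
STATOR_PERIOD = TWO_PI / 5.0
#: Angular period of the FliG rotor ring (26 subunits), rad.
ROTOR_PERIOD = TWO_PI / 26.0
#: Gear ratio k = rotor period / stator period = 5/26.
GEAR_RATIO = 5.0 / 26.0

logger = logging.getLogger("bfmsim")

# Short per-field help used by config validation and the CLI.
FIELD_HELP = {
    "delta_theta_S": "stator (MotA ring) period, rad; fixed at 2*pi/5",
    "delta_theta_R": "rotor (FliG ring) period, rad; fixed at 2*pi/26",
    "gear_ratio_k": "gear ratio delta_theta_R/delta_theta_S; fixed at 5/26",
    "U_S": "depth of each MotA-MotB well ramp, kBT",
    "U_R": "amplitude of the MotA-FliG coupling potential, kBT",
    "U_barrier": "height of the back-flow barrier, kBT",
    "barrier_width": "angular extent of the back-flow barrier rise, rad",
    "plateau_fraction": "fraction of the stator period that is flat",
    "k0": "chemical stepping rate inside the transition window, 1/time",
    "window_width": "half-width of the stepping window around the well minimum, rad",
    "xi_S": "stator rotational drag, kBT*time/rad^2",
    "xi_R": "rotor rotational drag (the load), kBT*time/rad^2",
    "kBT": "thermal energy (model energy unit)",
    "dt": "integration time step",
    "t_total": "total simulated duration",
    "sample_every": "store every n-th integration step",
    "seed": "RNG seed",
}

_INT_FIELDS = {"sample_every", "seed"}


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """All physical and numerical constants of the two-ring motor model.

    Validation happens at construction: ring periods and the gear ratio are
    pinned to the 5:26 stoichiometry, energies and rates must be
    non-negative (zero is allowed so that degenerate limits -- no noise, no
    chemistry, flat potentials -- remain expressible for validation), drag
    coefficients and time scales must be strictly positive, and the time
    step must satisfy both the first-order stepping-probability bound
    ``dt * k0 <= 0.1`` and a conservative drift-stability heuristic.
    """

    U_S: float = 15.0
    U_R: float = 15.0
    U_barrier: float = 30.0
    barrier_width: float = 0.1 * STATOR_PERIOD
    plateau_fraction: float = 0.5
    k0: float = 200.0
    window_width: float = 0.05 * STATOR_PERIOD
    xi_S: float = 0.1
    xi_R: float = 0.1
    kBT: float = 1.0
    dt: float = 5e-6
    t_total: float = 10.0
    sample_every: int = 80
    seed: int = 1
    delta_theta_S: float = STATOR_PERIOD
    delta_theta_R: float = ROTOR_PERIOD
    gear_ratio_k: float = GEAR_RATIO

    def __post_init__(self) -> None:
        if self.delta_theta_S != STATOR_PERIOD:
            raise ValueError("delta_theta_S must equal 2*pi/5 (5 MotA subunits)")
        if self.delta_theta_R != ROTOR_PERIOD:
            raise ValueError("delta_theta_R must equal 2*pi/26 (26 FliG subunits)")
        if self.gear_ratio_k != GEAR_RATIO:
            raise ValueError("gear_ratio_k must equal 5/26")
        if not math.isclose(
            self.gear_ratio_k, self.delta_theta_R / self.delta_theta_S, rel_tol=1e-12
        ):
            raise ValueError("gear_ratio_k must equal delta_theta_R/delta_theta_S")
        for name in ("U_S", "U_R", "U_barrier", "k0", "kBT"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        for name in ("xi_S", "xi_R", "dt", "t_total", "barrier_width"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0.0):
                raise ValueError(f"{name} must be finite and strictly positive, got {v}")
        if not 0.0 < self.plateau_fraction < 1.0:
            raise ValueError("plateau_fraction must lie strictly between 0 and 1")
        if not 0.0 < self.window_width < self.delta_theta_S / 2.0:
            raise ValueError("window_width must lie in (0, delta_theta_S/2)")
        if self.sample_every < 1:
            raise ValueError("sample_every must be a positive integer")
        if self.dt * self.k0 > 0.1:
            raise ValueError(
                "dt*k0 = {:.3g} exceeds 0.1: the first-order stepping probability "
                "km*dt is not a valid discretization at this time step".format(
                    self.dt * self.k0
                )
            )
        dt_max = self.stability_dt_bound()
        if self.dt > dt_max:
            raise ValueError(
                f"dt = {self.dt:g} exceeds the drift-stability bound {dt_max:g} "
                "(0.1 * min(xi) * delta_theta_R^2 / (kBT + max potential drop))"
            )

    def stability_dt_bound(self) -> float:
        """Conservative heuristic upper bound on the Euler-Maruyama step."""
        drop = max(self.U_S, self.U_R, self.U_barrier, 1e-12)
        return (
            0.1
            * min(self.xi_S, self.xi_R)
            * self.delta_theta_R**2
            / (self.kBT + drop)
        )

    # -- derived quantities ------------------------------------------------
    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    @property
    def ramp_start(self) -> float:
        """Angle (relative to a well's anchor) where the power-stroke ramp begins."""
        return self.plateau_fraction * self.delta_theta_S

    @property
    def ramp_slope(self) -> float:
        """Magnitude of dV/dx on the power-stroke ramp, kBT/rad."""
        return self.U_S / (self.delta_theta_S - self.ramp_start)

    @property
    def barrier_slope(self) -> float:
        return self.U_barrier / self.barrier_width

    def replace(self, **changes) -> "ModelParameters":
        """Return a validated copy with the given fields replaced."""
        try:
            return dataclasses.replace(self, **changes)
        except TypeError as exc:
            bad = sorted(set(changes) - {f.name for f in dataclasses.fields(self)})
            if bad:
                raise ValueError(f"unknown parameter key(s): {', '.join(bad)}") from exc
            raise

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict, base: "ModelParameters | None" = None) -> "ModelParameters":
        """Build parameters from a flat mapping, starting from ``base``.

        Unknown keys raise; missing keys fall back to ``base`` (or the
        defaults).  Integer fields reject non-integral values.
        """
        base = base if base is not None else cls()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown parameter key(s): {', '.join(unknown)}")
        coerced = {}
        for key, value in data.items():
            if key in _INT_FIELDS:
                if float(value) != int(value):
                    raise ValueError(f"{key} must be an integer, got {value}")
                coerced[key] = int(value)
            else:
                coerced[key] = float(value)
        return dataclasses.replace(base, **coerced)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path, base: "ModelParameters | None" = None) -> "ModelParameters":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a flat key-value mapping")
        return cls.from_dict(data, base=base)


@dataclasses.dataclass(frozen=True)
class Preset:
    """A named parameter bundle encoding one of the two studied regimes."""

    name: str
    params: ModelParameters

    def __post_init__(self) -> None:
        p = self.params
        if self.name == "comparable_potentials" and p.U_R != p.U_S:
            raise ValueError("comparable_potentials preset requires U_R == U_S")
        if self.name == "tight_coupling" and p.U_R < 10.0 * p.U_S:
            raise ValueError("tight_coupling preset requires U_R >= 10*U_S")


#: Shipped presets.  ``comparable_potentials`` has the MotA-FliG coupling as
#: strong as the MotA-MotB drive (slippage possible at high load);
#: ``tight_coupling`` makes the coupling ten times stronger (no slippage).
PRESETS: dict[str, Preset] = {
    "comparable_potentials": Preset("comparable_potentials", ModelParameters()),
    "tight_coupling": Preset(
        "tight_coupling",
        ModelParameters(U_S=5.0, U_R=50.0, U_barrier=20.0, dt=5e-6, sample_every=80),
    ),
}


def load_config(
    config_path=None,
    preset: str | None = None,
    overrides: dict | None = None,
) -> ModelParameters:
    """Resolve parameters with precedence: overrides > config file > preset.

    Every resolved value is logged at DEBUG level on the ``bfmsim`` logger.
    """
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(
                f"unknown preset '{preset}'; choose from {sorted(PRESETS)}"
            )
        base = PRESETS[preset].params
    else:
        base = ModelParameters()
    if config_path is not None:
        base = ModelParameters.from_yaml(config_path, base=base)
    if overrides:
        known = {f.name for f in dataclasses.fields(ModelParameters)}
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise ValueError(f"unknown parameter key(s): {', '.join(unknown)}")
        base = ModelParameters.from_dict(overrides, base=base)
    for key, value in base.to_dict().items():
        logger.debug("resolved parameter %s = %r", key, value)
    return base
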