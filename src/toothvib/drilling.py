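"""Physical parameterization of the drilled tooth.

Working unit system: grams, millimeters, seconds.  Forces are then in
g*mm/s^2 and the rigidity coefficient k (of the elastic force
``k * u * |u|**(alpha-1)``) in g*mm^(1-alpha)/s^2; in these units the
worked-example coefficients (k = 1, mass slope 0.002 g/s, drive 0.02) are
literal.  Spindle speed is stored in rev/s; rpm is converted at the boundary.

The drill removes tooth material at a constant volumetric rate, so the tooth
mass decreases linearly, ``m(t) = m0 - c*t`` with
``c = rho * D**2 * pi * n * f_r / 4``.  The mass loss produces a reactive
(Meshchersky) force ``(dM/dt) * u_dot``; the steady drilling force is
``F_f = K_f * D * f_r``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .gtf import GtfOrder

__all__ = [
    "ToothProperties",
    "DrillParameters",
    "MassSchedule",
    "InitialState",
    "DrillingSetup",
    "MassHorizonError",
    "mass_slope",
    "drilling_force",
    "reactive_force",
    "impact_initial_velocity",
    "initial_amplitude",
    "drill_frequency",
    "PRESETS",
    "load_config",
]

#: Validity windows quoted for human-tooth drilling; exceeding them warns.
DIAMETER_RANGE_MM = (1.0, 5.0)
SPINDLE_RANGE_RPM = (500.0, 2000.0)
FEED_RANGE_MM_PER_REV = (0.005, 0.06)


class MassHorizonError(ValueError):
    """Mass schedule evaluated at or past the time where the mass vanishes."""

    def __init__(self, t: float, critical_time: float):
        self.critical_time = critical_time
        super().__init__(
            f"mass is non-positive at t={t:g} s; the linear schedule is only "
            f"valid for t < m0/c = {critical_time:g} s"
        )


@dataclass(frozen=True)
class ToothProperties:
    """Tooth inertia and elasticity: mass m0 (g), rigidity k, order alpha."""

    m0: float
    k: float
    order: GtfOrder

    def __post_init__(self) -> None:
        if not isinstance(self.order, GtfOrder):
            object.__setattr__(self, "order", GtfOrder(float(self.order)))
        if not (self.m0 > 0 and self.k > 0):
            raise ValueError("tooth mass m0 and rigidity k must be positive")

    @property
    def alpha(self) -> float:
        return self.order.alpha


@dataclass(frozen=True)
class DrillParameters:
    """Drill-tool settings.

    D: diameter (mm); n: spindle speed (rev/s); f_r: feed rate (mm/rev);
    K_f: drilling-force coefficient (g/(mm*s^2) per mm of feed section, i.e.
    force per mm^2); rho: tooth density (g/mm^3).
    """

    D: float
    n: float
    f_r: float
    K_f: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("D", "n", "f_r", "K_f", "rho"):
            if not getattr(self, name) > 0:
                raise ValueError(f"drill parameter {name} must be strictly positive")
        self._warn_if_outside_ranges()

    def _warn_if_outside_ranges(self) -> None:
        checks = (
            ("D", self.D, DIAMETER_RANGE_MM, "mm"),
            ("spindle speed", self.rpm, SPINDLE_RANGE_RPM, "rpm"),
            ("f_r", self.f_r, FEED_RANGE_MM_PER_REV, "mm/rev"),
        )
        for name, value, (lo, hi), unit in checks:
            tol = 1e-9 * hi  # rev/s <-> rpm round-trips hit the bounds inexactly
            if not lo - tol <= value <= hi + tol:
                warnings.warn(
                    f"{name} = {value:g} {unit} is outside the usual tooth-"
                    f"drilling window [{lo:g}, {hi:g}] {unit}",
                    stacklevel=3,
                )

    @classmethod
    def from_rpm(cls, D: float, rpm: float, f_r: float, K_f: float, rho: float) -> "DrillParameters":
        return cls(D=D, n=rpm / 60.0, f_r=f_r, K_f=K_f, rho=rho)

    @property
    def rpm(self) -> float:
        return self.n * 60.0


@dataclass(frozen=True)
class MassSchedule:
    """Linear tooth-mass schedule m(t) = m0 - c*t (g, g/s)."""

    m0: float
    c: float

    def __post_init__(self) -> None:
        if not self.m0 > 0:
            raise ValueError("initial mass m0 must be positive")
        if self.c < 0:
            raise ValueError("mass-loss slope c must be non-negative")

    @classmethod
    def from_drill(cls, m0: float, params: DrillParameters) -> "MassSchedule":
        return cls(m0=m0, c=mass_slope(params))

    @property
    def critical_time(self) -> float:
        """Time at which the scheduled mass would vanish (inf if c = 0)."""
        return math.inf if self.c == 0 else self.m0 / self.c

    def mass_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Mass at time t; raises :class:`MassHorizonError` once depleted."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("mass schedule is defined for t >= 0 only")
        m = self.m0 - self.c * t_arr
        if np.any(m <= 0):
            bad = float(np.min(t_arr[np.asarray(m) <= 0]))
            raise MassHorizonError(bad, self.critical_time)
        return float(m) if np.isscalar(t) or t_arr.ndim == 0 else m


@dataclass(frozen=True)
class InitialState:
    """Initial axial deflection u0 (mm) and velocity v0 (mm/s)."""

    u0: float = 0.0
    v0: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u0) and np.isfinite(self.v0)):
            raise ValueError("initial state must be finite")


def mass_slope(params: DrillParameters) -> float:
    """Mass-loss rate c = rho * D^2 * pi * n * f_r / 4 (g/s).

    The drill of diameter D advancing f_r mm per revolution at n rev/s sweeps
    a cylinder of tooth material; quadratic in D, linear in n and f_r.
    """
    return params.rho * params.D**2 * math.pi * params.n * params.f_r / 4.0


def drilling_force(params: DrillParameters) -> float:
    """Steady axial drilling force F_f = K_f * D * f_r (g*mm/s^2)."""
    return params.K_f * params.D * params.f_r


def drilling_force_factor(params: DrillParameters) -> float:
    """The feed-scaled force factor F = K_f * D, so that F_f = f_r * F."""
    return params.K_f * params.D


def reactive_force(schedule: MassSchedule, velocity: float, t: float) -> float:
    """Reactive (Meshchersky) force (dM/dt) * u_dot = -c * u_dot.

    This is the force as defined for a body losing mass; moved to the right
    side of the equation of motion its contribution is ``+c * u_dot`` — for
    decreasing mass it pumps, rather than drains, oscillation energy.
    """
    schedule.mass_at(t)  # horizon check
    return -schedule.c * velocity


def impact_initial_velocity(F_f: float, n: float) -> float:
    """Initial tooth velocity v0 = F_f / n from the drill-impact momentum balance.

    A heuristic estimate (momentum transferred per revolution); n in rev/s.
    """
    if n <= 0:
        raise ValueError("spindle speed n must be positive")
    return F_f / n


def initial_amplitude(
    tooth: ToothProperties, state: InitialState, mode: str = "printed"
) -> float:
    """Initial vibration amplitude A(0) in the GTF ansatz.

    mode="printed" uses the kinetic-energy-only closed form

        A(0) = ((alpha+1)/2 * v0**2 / (k/m0)) ** (1/(alpha+1)),

    which ignores u0 (adequate when the initial deflection is small compared
    with the impact-driven amplitude).  mode="energy" adds the elastic energy
    of the initial deflection: A(0) = ((alpha+1)*m0*v0**2/(2k)
    + |u0|**(alpha+1)) ** (1/(alpha+1)).
    """
    a = tooth.alpha
    kinetic = (a + 1.0) / 2.0 * state.v0**2 * tooth.m0 / tooth.k
    if mode == "printed":
        return kinetic ** (1.0 / (a + 1.0))
    if mode == "energy":
        return (kinetic + abs(state.u0) ** (a + 1.0)) ** (1.0 / (a + 1.0))
    raise ValueError(f"unknown initial-amplitude mode {mode!r}")


def drill_frequency(n_rpm: float) -> float:
    """Drill rotation frequency Omega = pi * n / 30 rad/s for n in rpm."""
    if n_rpm <= 0:
        raise ValueError("spindle speed must be positive")
    return math.pi * n_rpm / 30.0


@dataclass(frozen=True)
class DrillingSetup:
    """Complete problem setup: tooth, mass schedule, initial state and drive.

    ``drive`` is the constant axial drilling force F_f = K_f * D * f_r in
    g*mm/s^2 (the right-hand-side constant of the equation of motion).
    """

    tooth: ToothProperties
    schedule: MassSchedule
    state: InitialState
    drive: float

    def __post_init__(self) -> None:
        if self.tooth.m0 != self.schedule.m0:
            raise ValueError("tooth.m0 and schedule.m0 disagree")
        if self.drive < 0:
            raise ValueError("drive force must be non-negative")

    @property
    def drive_over_k(self) -> float:
        """Static deflection scale eps*F/k of the drive (mm^alpha units)."""
        return self.drive / self.tooth.k

    def with_slope(self, c: float) -> "DrillingSetup":
        return replace(self, schedule=MassSchedule(self.schedule.m0, c))


def _molar_preset() -> DrillingSetup:
    """Worked example: 1.32 g molar, alpha = 1.03, k = 1 g/s^2, 2 mm drill.

    The mass slope 0.002 g/s and drive 0.02 g*mm/s^2 are taken as given
    (the density behind the slope is not part of the preset).
    """
    tooth = ToothProperties(m0=1.32, k=1.0, order=GtfOrder(1.03))
    return DrillingSetup(
        tooth=tooth,
        schedule=MassSchedule(m0=1.32, c=0.002),
        state=InitialState(u0=0.02, v0=0.5),
        drive=0.02,
    )


PRESETS: dict[str, "DrillingSetup"] = {}


def get_preset(name: str) -> DrillingSetup:
    """Return a named parameter preset (currently: ``molar``)."""
    try:
        factory = _PRESET_FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESET_FACTORIES)}"
        ) from None
    return factory()


_PRESET_FACTORIES = {"molar": _molar_preset}
PRESETS.update({name: f() for name, f in _PRESET_FACTORIES.items()})


_CONFIG_KEYS = {
    "m0", "k", "alpha", "D", "rpm", "f_r", "K_f", "rho",
    "u0", "v0", "mass_slope_override", "drive",
}


def setup_from_config(cfg: dict) -> DrillingSetup:
    """Build a :class:`DrillingSetup` from a flat key-value mapping.

    Recognized keys: m0, k, alpha (tooth); D, rpm, f_r, K_f, rho (drill);
    u0, v0 (initial state); mass_slope_override and drive bypass the drill
    chain.  The mass slope comes from the drill parameters unless overridden;
    the drive force from K_f*D*f_r unless given; v0 from the impact heuristic
    F_f/n unless given.
    """
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        tooth = ToothProperties(
            m0=float(cfg["m0"]), k=float(cfg["k"]), order=GtfOrder(float(cfg["alpha"]))
        )
    except KeyError as e:
        raise ValueError(f"config is missing required key {e.args[0]!r}") from None

    drill = None
    if all(k in cfg for k in ("D", "rpm", "f_r", "K_f", "rho")):
        drill = DrillParameters.from_rpm(
            D=float(cfg["D"]), rpm=float(cfg["rpm"]), f_r=float(cfg["f_r"]),
            K_f=float(cfg["K_f"]), rho=float(cfg["rho"]),
        )

    if "mass_slope_override" in cfg:
        c = float(cfg["mass_slope_override"])
    elif drill is not None:
        c = mass_slope(drill)
    else:
        raise ValueError(
            "config must supply either the full drill parameter set "
            "(D, rpm, f_r, K_f, rho) or mass_slope_override"
        )

    if "drive" in cfg:
        drive = float(cfg["drive"])
    elif drill is not None:
        drive = drilling_force(drill)
    else:
        raise ValueError("config must supply drive or the drill parameter set")

    if "v0" in cfg:
        v0 = float(cfg["v0"])
    elif drill is not None:
        v0 = impact_initial_velocity(drilling_force(drill), drill.n)
    else:
        v0 = 0.0

    state = InitialState(u0=float(cfg.get("u0", 0.0)), v0=v0)
    return DrillingSetup(
        tooth=tooth, schedule=MassSchedule(tooth.m0, c), state=state, drive=drive
    )


def load_config(path) -> DrillingSetup:
    """Load a flat YAML key-value config file into a :class:`DrillingSetup`."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must be a flat key-value mapping")
    return setup_from_config(cfg)
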