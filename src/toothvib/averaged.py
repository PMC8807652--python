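"""Closed-form averaged amplitude, frequency, phase and waveform.

Averaging the variable-mass oscillator over one GTF period turns the fast
dynamics into algebraic power laws in the instantaneous mass m(t).  With the
reactive force included the envelope and frequency both GROW as the mass is
drilled away,

    A(m)     = A(0) * (m0/m) ** (1/(alpha+3)),
    omega(m) = A(0)**((alpha-1)/2) * sqrt(2/(alpha+1))
               * (m0/m) ** ((alpha+1)/(alpha+3)) * sqrt(k/m0),

while dropping the reactive force reverses the amplitude trend
(A proportional to (m/m0)**(1/(alpha+3))), and a frozen mass gives constant
amplitude and frequency.  The slow phase is psi(t) = integral of
omega(m(t')) dt' and the displacement reconstructs through the GTF sine with
the constant drive folded in:

    u = ( A(t)**alpha * sin|sin|**(alpha-1) + F_f/k ) ** (1/alpha),

where the outer root is taken as a signed power so the expression stays real
and continuous when the bracket goes negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import cumulative_simpson

from .drilling import MassSchedule
from .gtf import GtfOrder, sin_gtf

__all__ = [
    "Regime",
    "EnvelopeLaw",
    "AnalyticTrajectory",
    "amplitude_with_reactive",
    "frequency_with_reactive",
    "amplitude_no_reactive",
    "frequency_no_reactive",
    "constant_mass_frequency",
    "accumulate_phase",
    "phase_closed_form",
    "waveform",
    "power_law_coefficients",
    "analytic_trajectory",
    "peak_displacement",
]

Regime = Literal["with_reactive", "no_reactive", "constant_mass"]


def _check_mass(m, m0) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be strictly positive")
    if np.any(m > m0 * (1 + 1e-12)):
        raise ValueError("mass cannot exceed the initial mass m0")
    return m


def amplitude_with_reactive(A0: float, m0: float, m, alpha: float):
    """Envelope A = A0 * (m0/m)**(1/(alpha+3)); grows as mass is removed.

    Independent of the rigidity k: mass loss feeds the envelope only through
    the reactive-force energy input.
    """
    m = _check_mass(m, m0)
    out = A0 * (m0 / m) ** (1.0 / (alpha + 3.0))
    return out if out.ndim else float(out)


def frequency_with_reactive(A0: float, m0: float, m, alpha: float, k: float):
    """Instantaneous frequency of the averaged solution, reactive force included.

    omega = A0**((alpha-1)/2) * sqrt(2/(alpha+1)) * (m0/m)**((alpha+1)/(alpha+3))
    * sqrt(k/m0); reduces to sqrt(k/m) exactly at alpha = 1.
    """
    m = _check_mass(m, m0)
    out = (
        A0 ** ((alpha - 1.0) / 2.0)
        * np.sqrt(2.0 / (alpha + 1.0))
        * (m0 / m) ** ((alpha + 1.0) / (alpha + 3.0))
        * np.sqrt(k / m0)
    )
    return out if out.ndim else float(out)


def amplitude_no_reactive(A0: float, m0: float, m, alpha: float):
    """Envelope with the reactive force omitted: A = A0 * (m/m0)**(1/(alpha+3)).

    The mirror image of :func:`amplitude_with_reactive` — the envelope decays
    as the mass is drilled away, which contradicts what is measured; keeping
    the reactive force matters.
    """
    m = _check_mass(m, m0)
    out = A0 * (m / m0) ** (1.0 / (alpha + 3.0))
    return out if out.ndim else float(out)


def frequency_no_reactive(
    A0: float, m0: float, m, alpha: float, k: float, mode: str = "printed"
):
    """Frequency with the reactive force omitted; two published readings.

    mode="printed" follows the stated law omega proportional to
    (m/m0)**((alpha+1)/(alpha+3)).  mode="consistent" substitutes the
    no-reactive envelope into omega = A**((alpha-1)/2) * sqrt(2k/((alpha+1)m)),
    which instead gives exponent -2/(alpha+3) on (m/m0) — i.e. a frequency
    that RISES slightly as m falls.  The two conflict; "printed" is the
    default for fidelity to the published relation, but neither is endorsed
    (see the package methods note).  Both coincide at m = m0.
    """
    m = _check_mass(m, m0)
    base = A0 ** ((alpha - 1.0) / 2.0) * np.sqrt(2.0 * k / ((alpha + 1.0) * m0))
    if mode == "printed":
        out = base * (m / m0) ** ((alpha + 1.0) / (alpha + 3.0))
    elif mode == "consistent":
        A = amplitude_no_reactive(A0, m0, m, alpha)
        out = np.asarray(A) ** ((alpha - 1.0) / 2.0) * np.sqrt(
            2.0 * k / ((alpha + 1.0) * m)
        )
    else:
        raise ValueError(f"unknown no-reactive frequency mode {mode!r}")
    out = np.asarray(out)
    return out if out.ndim else float(out)


def constant_mass_frequency(A0: float, alpha: float, k: float, m0: float) -> float:
    """Frequency when mass variation is neglected entirely.

    omega = A0**((alpha-1)/2) * sqrt(2k/((alpha+1)*m0)); the amplitude stays
    at A0.  At alpha = 1 this is the familiar natural frequency sqrt(k/m0).
    """
    return A0 ** ((alpha - 1.0) / 2.0) * np.sqrt(2.0 * k / ((alpha + 1.0) * m0))


@dataclass(frozen=True)
class EnvelopeLaw:
    """One regime's closed-form amplitude/frequency laws, bound to parameters."""

    regime: Regime
    A0: float
    alpha: float
    k: float
    m0: float
    freq_mode: str = "printed"

    def __post_init__(self) -> None:
        if self.regime not in ("with_reactive", "no_reactive", "constant_mass"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.A0 <= 0:
            raise ValueError("initial amplitude A0 must be positive")

    @property
    def amplitude_exponent(self) -> float:
        """Exponent of (m0/m) in the amplitude law (negative means decay)."""
        if self.regime == "with_reactive":
            return 1.0 / (self.alpha + 3.0)
        if self.regime == "no_reactive":
            return -1.0 / (self.alpha + 3.0)
        return 0.0

    @property
    def frequency_exponent(self) -> float:
        """Exponent of (m0/m) in the frequency law."""
        if self.regime == "with_reactive":
            return (self.alpha + 1.0) / (self.alpha + 3.0)
        if self.regime == "no_reactive":
            if self.freq_mode == "printed":
                return -(self.alpha + 1.0) / (self.alpha + 3.0)
            return 2.0 / (self.alpha + 3.0)
        return 0.0

    def amplitude(self, m):
        if self.regime == "with_reactive":
            return amplitude_with_reactive(self.A0, self.m0, m, self.alpha)
        if self.regime == "no_reactive":
            return amplitude_no_reactive(self.A0, self.m0, m, self.alpha)
        out = np.full_like(np.asarray(m, dtype=float), self.A0)
        return out if out.ndim else float(out)

    def frequency(self, m):
        if self.regime == "with_reactive":
            return frequency_with_reactive(self.A0, self.m0, m, self.alpha, self.k)
        if self.regime == "no_reactive":
            return frequency_no_reactive(
                self.A0, self.m0, m, self.alpha, self.k, mode=self.freq_mode
            )
        _check_mass(m, self.m0)
        out = np.full_like(
            np.asarray(m, dtype=float),
            constant_mass_frequency(self.A0, self.alpha, self.k, self.m0),
        )
        return out if out.ndim else float(out)


def power_law_coefficients(law: EnvelopeLaw) -> tuple[float, float]:
    """Rewrite the frequency law as omega(m) = C * m**p by rearrangement.

    No fitting: C collects every m-independent factor, p is read off the
    regime's exponent.  For the constant-mass regime p = 0 and C is the fixed
    frequency.  For the worked molar example this returns
    (C, p) = (0.98561, -0.50372).
    """
    omega0 = constant_mass_frequency(law.A0, law.alpha, law.k, law.m0)
    if law.regime == "constant_mass":
        return omega0, 0.0
    # omega(m) = omega0 * (m0/m)**q  =>  C = omega0 * m0**q, p = -q
    q = law.frequency_exponent
    return omega0 * law.m0**q, -q


def accumulate_phase(
    law: EnvelopeLaw,
    schedule: MassSchedule,
    t: np.ndarray,
    theta0: float = 0.0,
) -> np.ndarray:
    """Accumulated GTF phase psi(t) = theta0 + integral_0^t omega(m(t')) dt'.

    Composite-Simpson quadrature on the supplied grid (the slow phase
    correction theta is identically zero under averaging, so psi is driven by
    omega alone).  The grid must start at 0, increase, and stay inside the
    mass-schedule horizon.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be 1-D, increasing and start at 0")
    omega = np.asarray(law.frequency(schedule.mass_at(t)))
    return theta0 + cumulative_simpson(omega, x=t, initial=0.0)


def phase_closed_form(
    law: EnvelopeLaw,
    schedule: MassSchedule,
    t: np.ndarray,
    theta0: float = 0.0,
) -> np.ndarray:
    """Exact phase for a linear mass schedule via the power-law antiderivative.

    With omega(m) = C*m**p and m = m0 - c*t,
    psi = theta0 + C/(c*(p+1)) * (m0**(p+1) - (m0-c*t)**(p+1)) for c > 0,
    and theta0 + omega(m0)*t for c = 0.  Serves as the quadrature oracle.
    """
    t = np.asarray(t, dtype=float)
    C, p = power_law_coefficients(law)
    if schedule.c == 0:
        return theta0 + C * schedule.m0**p * t
    m = np.asarray(schedule.mass_at(t))
    return theta0 + C / (schedule.c * (p + 1.0)) * (
        schedule.m0 ** (p + 1.0) - m ** (p + 1.0)
    )


def _signed_power(y: np.ndarray, q: float) -> np.ndarray:
    return np.sign(y) * np.abs(y) ** q


def waveform(
    A: np.ndarray,
    psi: np.ndarray,
    alpha: float,
    drive_over_k: float = 0.0,
    order: GtfOrder | None = None,
) -> np.ndarray:
    """Displacement u(t) from envelope and phase.

    u = signed_root_alpha( A**alpha * sin|sin|**(alpha-1) + F_f/k ), with
    sin = sin_{2,alpha+1}(psi).  For alpha = 1 this is exactly
    A*sin(psi) + F_f/k.  ``A`` and ``psi`` must share a grid.
    """
    A = np.asarray(A, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if A.shape != psi.shape:
        raise ValueError(f"grid mismatch: A has shape {A.shape}, psi {psi.shape}")
    order = order if order is not None else GtfOrder(alpha)
    s = np.asarray(sin_gtf(order, psi))
    bracket = A**alpha * _signed_power(s, alpha) + drive_over_k
    return _signed_power(bracket, 1.0 / alpha)


@dataclass(frozen=True)
class AnalyticTrajectory:
    """Sampled closed-form solution: envelope, frequency, phase, displacement."""

    t: np.ndarray
    m: np.ndarray
    A: np.ndarray
    omega: np.ndarray
    psi: np.ndarray
    u: np.ndarray
    law: EnvelopeLaw
    drive_over_k: float = 0.0

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("m", "A", "omega", "psi", "u"):
            if getattr(self, name).size != n:
                raise ValueError(f"field {name} length differs from time grid")


def analytic_trajectory(
    law: EnvelopeLaw,
    schedule: MassSchedule,
    t: np.ndarray,
    drive_over_k: float = 0.0,
    theta0: float = 0.0,
) -> AnalyticTrajectory:
    """Evaluate the full averaged solution on a time grid."""
    t = np.asarray(t, dtype=float)
    m = np.asarray(schedule.mass_at(t))
    A = np.asarray(law.amplitude(m))
    omega = np.asarray(law.frequency(m))
    psi = accumulate_phase(law, schedule, t, theta0=theta0)
    u = waveform(A, psi, law.alpha, drive_over_k=drive_over_k)
    return AnalyticTrajectory(
        t=t, m=m, A=A, omega=omega, psi=psi, u=u, law=law, drive_over_k=drive_over_k
    )


def peak_displacement(law: EnvelopeLaw, m, drive_over_k: float = 0.0):
    """Per-cycle positive peak of u: the waveform at sin_{2,alpha+1} = 1.

    u_peak(m) = (A(m)**alpha + F_f/k)**(1/alpha); the envelope against which
    numerically extracted peaks are compared.
    """
    A = np.asarray(law.amplitude(m))
    out = _signed_power(A**law.alpha + drive_over_k, 1.0 / law.alpha)
    return out if out.ndim else float(out)
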