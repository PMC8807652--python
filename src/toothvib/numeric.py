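"""Direct numerical integration of the variable-mass oscillator.

Ground truth for the averaged closed forms: the full equation of motion

    m(t) * u'' + k * u * |u|**(alpha-1) = c * u' + F_f,      m(t) = m0 - c*t,

is integrated with an adaptive high-order Runge-Kutta pair (DOP853 by
default) at tight tolerances, and a fixed-step classical RK4 integrator is
kept as a second, independent route.  Envelope extraction (per-cycle peak
amplitudes and periods) turns trajectories into the quantities the averaged
laws predict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.ndimage import uniform_filter1d

from .averaged import AnalyticTrajectory
from .drilling import DrillingSetup, InitialState, MassSchedule, ToothProperties
from .gtf import GtfOrder, full_period

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "Envelope",
    "InsufficientDataError",
    "simulate",
    "simulate_setup",
    "simulate_gtf",
    "extract_envelope",
    "compare",
    "ComparisonReport",
]


class InsufficientDataError(ValueError):
    """Trajectory too short or too sparsely sampled for envelope extraction."""


@dataclass(frozen=True)
class SimulationConfig:
    """Integrator settings.

    dt is the output grid spacing (the integrator steps adaptively
    underneath); keep it small enough for >= 40 samples per oscillation
    cycle if the trajectory will feed envelope extraction.  method is
    "DOP853" (adaptive 8th-order, default) or "RK4" (fixed-step classical,
    stepping at dt/rk4_substeps; the independent cross-check route).
    """

    t_end: float
    dt: float = 0.02
    rtol: float = 1e-10
    atol: float = 1e-12
    max_step: float = math.inf
    method: str = "DOP853"
    rk4_substeps: int = 20

    def __post_init__(self) -> None:
        if not (self.t_end > 0 and self.dt > 0):
            raise ValueError("t_end and dt must be positive")
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("tolerances must be positive")
        if self.method not in ("DOP853", "RK45", "RK4"):
            raise ValueError(f"unsupported method {self.method!r}")

    @property
    def t_eval(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt))
        return np.linspace(0.0, n * self.dt, n + 1)


@dataclass(frozen=True)
class Trajectory:
    """Sampled numeric solution: t (s), u (mm), udot (mm/s), m (g)."""

    t: np.ndarray
    u: np.ndarray
    udot: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        if not (self.t.size == self.u.size == self.udot.size == self.m.size):
            raise ValueError("trajectory arrays must share one grid")
        if np.any(self.m <= 0):
            raise ValueError("trajectory contains non-positive mass")


def _rk4(f: Callable, y0: np.ndarray, t_grid: np.ndarray, substeps: int) -> np.ndarray:
    """Classical fixed-step 4th-order Runge-Kutta on a uniform output grid."""
    y = np.empty((t_grid.size, y0.size))
    y[0] = y0
    for i in range(t_grid.size - 1):
        t, h = t_grid[i], (t_grid[i + 1] - t_grid[i]) / substeps
        yi = y[i]
        for _ in range(substeps):
            k1 = f(t, yi)
            k2 = f(t + h / 2, yi + h / 2 * k1)
            k3 = f(t + h / 2, yi + h / 2 * k2)
            k4 = f(t + h, yi + h * k3)
            yi = yi + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        y[i + 1] = yi
    return y


def simulate(
    tooth: ToothProperties,
    schedule: MassSchedule,
    drive: float,
    state: InitialState,
    config: SimulationConfig,
    include_reactive: bool = True,
) -> Trajectory:
    """Integrate m(t)*u'' + k*u|u|**(alpha-1) = c*u' + F_f from (u0, v0).

    ``include_reactive=False`` drops the reactive term c*u' from the right
    side while keeping the mass variation in the inertia — the regime used to
    demonstrate that neglecting the reactive force reverses the envelope
    trend.  Raises if the horizon reaches the mass-depletion time.
    """
    if config.t_end >= schedule.critical_time:
        raise ValueError(
            f"t_end={config.t_end:g} s reaches the mass-depletion time "
            f"m0/c = {schedule.critical_time:g} s"
        )
    k, alpha = tooth.k, tooth.alpha
    c_react = schedule.c if include_reactive else 0.0

    def rhs(t, y):
        u, v = y
        m = schedule.m0 - schedule.c * t
        acc = (-k * u * abs(u) ** (alpha - 1.0) + c_react * v + drive) / m
        return np.array([v, acc])

    y0 = np.array([state.u0, state.v0], dtype=float)
    t_eval = config.t_eval
    if config.method == "RK4":
        y = _rk4(rhs, y0, t_eval, config.rk4_substeps)
        u, v = y[:, 0], y[:, 1]
    else:
        sol = solve_ivp(
            rhs,
            (0.0, t_eval[-1]),
            y0,
            method=config.method,
            t_eval=t_eval,
            rtol=config.rtol,
            atol=config.atol,
            max_step=config.max_step,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        u, v = sol.y
    return Trajectory(t=t_eval, u=u, udot=v, m=schedule.mass_at(t_eval))


def simulate_setup(
    setup: DrillingSetup, config: SimulationConfig, include_reactive: bool = True
) -> Trajectory:
    """Convenience wrapper: simulate a bundled :class:`DrillingSetup`."""
    return simulate(
        setup.tooth, setup.schedule, setup.drive, setup.state, config,
        include_reactive=include_reactive,
    )


def simulate_gtf(
    alpha: float, K: float, t_end: float, dt: float = 0.005,
    rtol: float = 1e-12, atol: float = 1e-14,
) -> Trajectory:
    """Integrate the pure-nonlinear oscillator x'' + K*x|x|**(alpha-1) = 0.

    Initial conditions x(0) = 0, x'(0) = 1.  With K = (alpha+1)/2 the
    solution is exactly sin_{2,alpha+1}(t); the independent oracle for the
    GTF evaluator.  The mass column is a placeholder unit mass.
    """
    if K <= 0:
        raise ValueError("stiffness K must be positive")
    cfg = SimulationConfig(t_end=t_end, dt=dt, rtol=rtol, atol=atol)
    tooth = ToothProperties(m0=1.0, k=K, order=GtfOrder(alpha))
    schedule = MassSchedule(m0=1.0, c=0.0)
    return simulate(tooth, schedule, 0.0, InitialState(u0=0.0, v0=1.0), cfg)


@dataclass(frozen=True)
class Envelope:
    """Per-cycle summary of an oscillatory trajectory.

    peak_times/peak_values: refined local maxima of u.  period_times/periods:
    per-cycle periods from successive upward zero crossings of the detrended
    signal (crossing-interval midpoints as time stamps).  freq_circular is
    2*pi/period; freq_gtf, when an order was supplied, is 2*Pi_alpha/period —
    the frequency in the GTF's own phase units, the one the averaged laws
    predict.
    """

    peak_times: np.ndarray
    peak_values: np.ndarray
    period_times: np.ndarray
    periods: np.ndarray
    freq_circular: np.ndarray
    freq_gtf: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if np.any(self.periods <= 0):
            raise ValueError("periods must be positive")


def _refine_peak(t: np.ndarray, u: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic refinement through three samples around a discrete maximum."""
    denom = u[i - 1] - 2.0 * u[i] + u[i + 1]
    if denom == 0.0:
        return t[i], u[i]
    delta = 0.5 * (u[i - 1] - u[i + 1]) / denom
    dt = t[i + 1] - t[i]
    return t[i] + delta * dt, u[i] - 0.25 * (u[i - 1] - u[i + 1]) * delta


def extract_envelope(traj: Trajectory, alpha: float | None = None) -> Envelope:
    """Locate per-cycle peaks and periods of a sampled trajectory.

    Peaks: 3-point local-maximum test refined by parabolic interpolation.
    Periods: successive upward zero crossings of u minus a one-cycle running
    mean (which neutralizes the constant drive offset F_f/k), with linear
    interpolation between samples.  Requires at least two peaks and at least
    ~40 samples per cycle for trustworthy refinement.
    """
    t, u = traj.t, traj.u
    interior = np.flatnonzero(
        (u[1:-1] > u[:-2]) & (u[1:-1] >= u[2:])
    ) + 1
    if interior.size < 2:
        raise InsufficientDataError(
            f"found {interior.size} peak(s); need at least 2 for an envelope"
        )
    refined = np.array([_refine_peak(t, u, i) for i in interior])
    peak_times, peak_values = refined[:, 0], refined[:, 1]

    # running mean over roughly one cycle
    spacing = float(np.median(np.diff(peak_times)))
    dt = float(t[1] - t[0])
    window = max(3, int(round(spacing / dt)) | 1)
    detrended = u - uniform_filter1d(u, size=window, mode="nearest")

    up = np.flatnonzero((detrended[:-1] < 0.0) & (detrended[1:] >= 0.0))
    # the running mean is edge-biased within half a window of either end;
    # crossings there give distorted periods and are discarded
    margin = window // 2
    up = up[(up >= margin) & (up < t.size - 1 - margin)]
    if up.size < 2:
        raise InsufficientDataError("fewer than two upward zero crossings")
    frac = -detrended[up] / (detrended[up + 1] - detrended[up])
    crossings = t[up] + frac * (t[up + 1] - t[up])
    periods = np.diff(crossings)
    period_times = 0.5 * (crossings[:-1] + crossings[1:])
    freq_circ = 2.0 * math.pi / periods
    freq_gtf = full_period(alpha) / periods if alpha is not None else None
    return Envelope(
        peak_times=peak_times,
        peak_values=peak_values,
        period_times=period_times,
        periods=periods,
        freq_circular=freq_circ,
        freq_gtf=freq_gtf,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Analytic-vs-numeric error metrics on a common time window.

    envelope_rel_errors pairs each numeric peak (within the window) with the
    analytic peak envelope interpolated to the same time; exceed_time is the
    first peak time where that error passes the threshold (None if never).
    """

    window: tuple[float, float]
    max_abs_u_diff: float
    peak_times: np.ndarray
    envelope_rel_errors: np.ndarray
    max_envelope_rel_error: float
    max_period_rel_error: float
    threshold: float
    exceed_time: float | None

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "max_abs_u_diff": self.max_abs_u_diff,
            "max_envelope_rel_error": self.max_envelope_rel_error,
            "max_period_rel_error": self.max_period_rel_error,
            "threshold": self.threshold,
            "exceed_time": self.exceed_time,
            "per_cycle": [
                {"t": float(tt), "envelope_rel_error": float(ee)}
                for tt, ee in zip(self.peak_times, self.envelope_rel_errors)
            ],
        }


def compare(
    analytic: AnalyticTrajectory,
    numeric: Trajectory,
    threshold: float = 0.05,
    alpha: float | None = None,
) -> ComparisonReport:
    """Quantify how well the averaged solution tracks the direct integration.

    Reports the pointwise max |u| difference (phase drift makes this grow
    long before the envelopes disagree), the per-cycle relative envelope
    error and the per-cycle relative period error, each computed from
    independently extracted envelopes matched in time by interpolation.
    """
    lo = max(analytic.t[0], numeric.t[0])
    hi = min(analytic.t[-1], numeric.t[-1])
    if hi <= lo:
        raise ValueError("analytic and numeric trajectories share no time window")
    sel = (numeric.t >= lo) & (numeric.t <= hi)
    u_interp = np.interp(numeric.t[sel], analytic.t, analytic.u)
    max_diff = float(np.max(np.abs(u_interp - numeric.u[sel])))

    env_n = extract_envelope(numeric, alpha=alpha)
    env_a = extract_envelope(
        Trajectory(t=analytic.t, u=analytic.u,
                   udot=np.zeros_like(analytic.u), m=analytic.m),
        alpha=alpha,
    )
    keep = (
        (env_n.peak_times >= max(lo, env_a.peak_times[0]))
        & (env_n.peak_times <= min(hi, env_a.peak_times[-1]))
    )
    pt = env_n.peak_times[keep]
    a_at_n = np.interp(pt, env_a.peak_times, env_a.peak_values)
    env_err = np.abs(a_at_n - env_n.peak_values[keep]) / np.abs(env_n.peak_values[keep])

    keep_p = (
        (env_n.period_times >= max(lo, env_a.period_times[0]))
        & (env_n.period_times <= min(hi, env_a.period_times[-1]))
    )
    p_at_n = np.interp(env_n.period_times[keep_p], env_a.period_times, env_a.periods)
    period_err = np.abs(p_at_n - env_n.periods[keep_p]) / env_n.periods[keep_p]

    over = np.flatnonzero(env_err > threshold)
    return ComparisonReport(
        window=(float(lo), float(hi)),
        max_abs_u_diff=max_diff,
        peak_times=pt,
        envelope_rel_errors=env_err,
        max_envelope_rel_error=float(np.max(env_err)) if env_err.size else math.nan,
        max_period_rel_error=float(np.max(period_err)) if period_err.size else math.nan,
        threshold=threshold,
        exceed_time=float(pt[over[0]]) if over.size else None,
    )
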