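"""Parameter sweeps and drilling-parameter effect reports.

Normalized figure-style tables: amplitude ratio A/A0 and frequency ratio
omega/omega0 against the mass ratio m0/m for several nonlinearity orders,
plus a drill-parameter report chaining diameter, spindle speed and feed rate
through the force/impact/amplitude formulas.  Everything here is
deterministic; outputs are CSV with a JSON run-manifest sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .drilling import (
    DrillParameters,
    InitialState,
    ToothProperties,
    drilling_force,
    impact_initial_velocity,
    initial_amplitude,
    mass_slope,
)

__all__ = [
    "SweepSpec",
    "RunManifest",
    "run_amplitude_sweep",
    "run_frequency_sweep",
    "run_drill_effect_report",
    "write_table",
]


@dataclass(frozen=True)
class SweepSpec:
    """Grid of mass ratios m0/m >= 1 and the nonlinearity orders to sweep."""

    ratios: np.ndarray
    alphas: tuple[float, ...] = (1.01, 1.05, 1.1)

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if r.size == 0 or np.any(r < 1.0):
            raise ValueError("mass-ratio grid must be nonempty with m0/m >= 1")
        if len(self.alphas) == 0 or any(a < 1.0 for a in self.alphas):
            raise ValueError("need at least one alpha >= 1")
        object.__setattr__(self, "ratios", r)

    @classmethod
    def linear(
        cls, ratio_max: float = 2.0, n: int = 101,
        alphas: tuple[float, ...] = (1.01, 1.05, 1.1),
    ) -> "SweepSpec":
        return cls(ratios=np.linspace(1.0, ratio_max, n), alphas=tuple(alphas))


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility sidecar: resolved parameters, version, config hash."""

    params: dict
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.params, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def write_sidecar(self, out_path: str | Path) -> Path:
        path = Path(str(out_path) + ".manifest.json")
        path.write_text(
            json.dumps(
                {
                    "params": self.params,
                    "version": self.version,
                    "timestamp": self.timestamp,
                    "config_hash": self.config_hash,
                },
                indent=2,
                default=str,
            )
            + "\n"
        )
        return path


def run_amplitude_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Normalized envelope A/A0 = (m0/m)**(1/(alpha+3)) per mass ratio and alpha.

    Grows with the mass ratio for every order; at fixed ratio the growth is
    faster for lower alpha (the exponent 1/(alpha+3) shrinks with alpha).
    """
    data = {"mass_ratio": spec.ratios}
    for a in spec.alphas:
        data[f"alpha={a:g}"] = spec.ratios ** (1.0 / (a + 3.0))
    return pd.DataFrame(data)


def run_frequency_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Normalized frequency omega/omega0 = (m0/m)**((alpha+1)/(alpha+3)).

    The reactive-force regime's frequency law; equals sqrt(mass ratio)
    exactly for alpha = 1.
    """
    data = {"mass_ratio": spec.ratios}
    for a in spec.alphas:
        data[f"alpha={a:g}"] = spec.ratios ** ((a + 1.0) / (a + 3.0))
    return pd.DataFrame(data)


def run_drill_effect_report(
    tooth: ToothProperties,
    K_f: float,
    rho: float,
    diameters: np.ndarray | None = None,
    rpms: np.ndarray | None = None,
    feed_rates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate how drill settings shape the vibration.

    For every (D, rpm, f_r) combination the chain is: drilling force
    F_f = K_f*D*f_r, impact velocity v0 = F_f/n, initial amplitude A(0), and
    mass slope c = rho*D^2*pi*n*f_r/4 (the envelope-growth driver).  Larger
    diameter and feed raise both the force and the mass-loss rate; faster
    spindles lower the impact amplitude but speed up the mass loss.
    """
    D_grid = np.asarray(diameters if diameters is not None else np.linspace(1, 5, 5), float)
    rpm_grid = np.asarray(rpms if rpms is not None else np.linspace(500, 2000, 4), float)
    fr_grid = np.asarray(
        feed_rates if feed_rates is not None else np.linspace(0.005, 0.06, 4), float
    )
    rows = []
    for D in D_grid:
        for rpm in rpm_grid:
            for f_r in fr_grid:
                params = DrillParameters.from_rpm(D=D, rpm=rpm, f_r=f_r, K_f=K_f, rho=rho)
                F_f = drilling_force(params)
                v0 = impact_initial_velocity(F_f, params.n)
                A0 = initial_amplitude(tooth, InitialState(u0=0.0, v0=v0))
                rows.append(
                    {
                        "D_mm": D, "rpm": rpm, "f_r_mm_per_rev": f_r,
                        "F_f": F_f, "v0_mm_per_s": v0, "A0_mm": A0,
                        "mass_slope_g_per_s": mass_slope(params),
                    }
                )
    df = pd.DataFrame(rows)
    _check_orderings(df)
    return df


def _check_orderings(df: pd.DataFrame) -> None:
    """Assert the qualitative drill-parameter effects the model predicts."""
    for (rpm, fr), g in df.groupby(["rpm", "f_r_mm_per_rev"]):
        g = g.sort_values("D_mm")
        if not (g["A0_mm"].is_monotonic_increasing and g["mass_slope_g_per_s"].is_monotonic_increasing):
            raise AssertionError("A0 and mass slope must increase with drill diameter")
    for (D, fr), g in df.groupby(["D_mm", "f_r_mm_per_rev"]):
        g = g.sort_values("rpm")
        if not g["A0_mm"].is_monotonic_decreasing:
            raise AssertionError("A0 must decrease with spindle speed (v0 = F_f/n)")
        if not g["mass_slope_g_per_s"].is_monotonic_increasing:
            raise AssertionError("mass slope must increase with spindle speed")


def write_table(df: pd.DataFrame, out_path: str | Path, params: dict) -> Path:
    """Write a CSV table plus its :class:`RunManifest` sidecar."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, index=False)
    RunManifest(params=params).write_sidecar(out_path)
    return out_path
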