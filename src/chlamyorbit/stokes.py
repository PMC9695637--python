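"""Low-Reynolds-number force model of the revolving monoflagellate cell.

The cell body is treated as a sphere of radius ``r`` in creeping flow. The
single flagellum exerts a beat-averaged force of magnitude ``F`` at angle
``θ`` from the surface normal at its base; the normal component drives the
revolution (translation of the centre on a circle of radius ``R`` at
angular velocity ``ω``) and the tangential component drives the spin, which
is phase-locked to the revolution. Balancing each against the Stokes drag
force ``6πηrv`` and drag torque ``8πηr³ω``:

    F cosθ = 6πηrRω          (translation / revolution)
    r F sinθ = 8πηr³ω        (rotation / spin)

so ``tanθ = 4r/(3R)`` independently of η and ω, and the power input
``F cosθ·Rω + F sinθ·rω`` equals the viscous dissipation identically.

For the intact biflagellate cell the two flagella sit at a central angle
``α`` (default 20°, measured from micrographs) on the equator; each
contributes ``F cos(θ − α/2)`` along the swimming direction, giving the
predicted straight-swimming speed

    v = 2 F cos(θ − α/2) / (6πηr) = F cos(θ − α/2) / (3πηr).

All computation is in SI units; reporting helpers convert to pN and μm/s.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .kinematics import (CellKinematics, analyze_tracks, summarize_population)
from .tracks import Track

__all__ = [
    "CellGeometry",
    "FluidParams",
    "ForceSolution",
    "solve_monoflagellate",
    "energy_balance_residual",
    "predict_biflagellate_velocity",
    "end_to_end",
    "load_reference_cells",
]

#: cell radius (m) and flagellar central angle (rad) used throughout
DEFAULT_CELL_RADIUS_M = 5e-6
DEFAULT_ALPHA_RAD = math.radians(20.0)
#: dynamic viscosity of water at the recording temperature (Pa·s)
DEFAULT_ETA = 1.002e-3


@dataclasses.dataclass(frozen=True)
class CellGeometry:
    """Spherical cell body of radius ``r`` (m) with flagellar bases ``alpha``
    radians apart on the equator."""

    r: float = DEFAULT_CELL_RADIUS_M
    alpha: float = DEFAULT_ALPHA_RAD

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"cell radius must be positive, got {self.r!r}")
        if not 0 < self.alpha < math.pi:
            raise ValueError(f"alpha must be in (0, π) rad, got {self.alpha!r}")


@dataclasses.dataclass(frozen=True)
class FluidParams:
    """Newtonian fluid with dynamic viscosity ``eta`` (Pa·s)."""

    eta: float = DEFAULT_ETA

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError(f"viscosity must be positive, got {self.eta!r}")


@dataclasses.dataclass
class ForceSolution:
    """Per-flagellum driving force and derived biflagellate prediction (SI).

    ``F_cos``/``F_sin`` are the normal/tangential force components (N),
    ``theta`` the force angle from the surface normal (rad), ``F`` the
    magnitude. The biflagellate fields are filled by
    :func:`predict_biflagellate_velocity`.
    """

    F_cos: float
    F_sin: float
    theta: float
    F: float
    v_biflagellate: float | None = None   # m/s
    propulsion_bi: float | None = None    # N, 2F·cos(θ − α/2)
    F_sum: float | None = None            # N, 2F
    drag_coeff_half: float | None = None  # kg/s, 3πηr


def solve_monoflagellate(R: float, omega: float,
                         geom: CellGeometry = CellGeometry(),
                         fluid: FluidParams = FluidParams()) -> ForceSolution:
    """Solve the translation and rotation balances for F and θ.

    Parameters are SI: ``R`` in metres, ``omega`` in rad/s (magnitude).
    """
    if not R > 0:
        raise ValueError(f"revolution radius must be positive, got {R!r} "
                         "(θ is undefined at R = 0)")
    if not omega > 0:
        raise ValueError(f"angular velocity must be positive, got {omega!r} "
                         "(a non-moving cell exerts no resolvable force)")
    F_cos = 6 * math.pi * fluid.eta * geom.r * R * omega
    F_sin = 8 * math.pi * fluid.eta * geom.r ** 2 * omega
    theta = math.atan2(F_sin, F_cos)  # == arctan(4r / (3R))
    F = math.hypot(F_cos, F_sin)
    return ForceSolution(F_cos=F_cos, F_sin=F_sin, theta=theta, F=F)


def energy_balance_residual(sol: ForceSolution, R: float, omega: float,
                            geom: CellGeometry = CellGeometry(),
                            fluid: FluidParams = FluidParams()) -> float:
    """Relative residual of the power balance.

    Input power ``F cosθ·Rω + F sinθ·rω`` versus viscous dissipation
    ``6πηr(Rω)² + 8πηr³ω²``; identically zero (to round-off) for a solution
    of the two balances.
    """
    lhs = sol.F_cos * R * omega + sol.F_sin * geom.r * omega
    rhs = (6 * math.pi * fluid.eta * geom.r * (R * omega) ** 2
           + 8 * math.pi * fluid.eta * geom.r ** 3 * omega ** 2)
    return abs(lhs - rhs) / rhs


def predict_biflagellate_velocity(sol: ForceSolution,
                                  geom: CellGeometry = CellGeometry(),
                                  fluid: FluidParams = FluidParams()) -> float:
    """Predicted straight-swimming speed of the biflagellate cell (m/s).

    Fills the biflagellate fields of ``sol`` (projected propulsion
    ``2F·cos(θ − α/2)``, plain sum ``2F``, half drag coefficient ``3πηr``)
    and returns ``v = F·cos(θ − α/2) / (3πηr)``.
    """
    beta = sol.theta - geom.alpha / 2
    if not -math.pi / 2 < beta < math.pi / 2:
        raise ValueError(
            f"projection angle θ − α/2 = {beta:.3f} rad outside (−π/2, π/2); "
            "the propulsion model does not apply")
    drag_half = 3 * math.pi * fluid.eta * geom.r
    projected = sol.F * math.cos(beta)
    v = projected / drag_half
    sol.v_biflagellate = v
    sol.propulsion_bi = 2 * projected
    sol.F_sum = 2 * sol.F
    sol.drag_coeff_half = drag_half
    return v


def load_reference_cells() -> pd.DataFrame:
    """Published per-cell (ω, R) measurements shipped with the package.

    Columns: ``cell``, ``omega_rad_s``, ``R_um`` — twelve revolving
    monoflagellate cells measured by high-speed video tracking.
    """
    ref = importlib.resources.files("chlamyorbit.data") / "reference_cells.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def reference_kinematics() -> list[CellKinematics]:
    """The reference measurements as CellKinematics records."""
    df = load_reference_cells()
    return [
        CellKinematics(track_id=int(row.cell), R=float(row.R_um),
                       omega=float(row.omega_rad_s), direction="ccw",
                       center=(0.0, 0.0), fit_residual=0.0)
        for row in df.itertuples()
    ]


def _solution_report(sol: ForceSolution) -> dict:
    rep = {
        "F_cos_N": sol.F_cos,
        "F_sin_N": sol.F_sin,
        "tan_theta": sol.F_sin / sol.F_cos,
        "theta_deg": math.degrees(sol.theta),
        "F_N": sol.F,
        "F_cos_pN": sol.F_cos * 1e12,
        "F_sin_pN": sol.F_sin * 1e12,
        "F_pN": sol.F * 1e12,
    }
    if sol.v_biflagellate is not None:
        rep.update({
            "v_biflagellate_m_s": sol.v_biflagellate,
            "v_biflagellate_um_s": sol.v_biflagellate * 1e6,
            "propulsion_bi_N": sol.propulsion_bi,
            "propulsion_bi_pN": sol.propulsion_bi * 1e12,
            "F_sum_N": sol.F_sum,
            "F_sum_pN": sol.F_sum * 1e12,
            "drag_coeff_half_kg_s": sol.drag_coeff_half,
            "projected_force_N": sol.propulsion_bi / 2,
            "projected_force_pN": sol.propulsion_bi / 2 * 1e12,
        })
    return rep


def end_to_end(cells: Sequence[CellKinematics] | Sequence[Track],
               geom: CellGeometry = CellGeometry(),
               fluid: FluidParams = FluidParams(),
               provenance: dict | None = None) -> dict:
    """Population mean (R, ω) → force solution → biflagellate prediction.

    ``cells`` may be per-cell kinematics, or raw tracks which are then
    classified and fitted first (only revolving cells enter the mean).
    Returns a JSON-serialisable report.
    """
    items = list(cells)
    if items and isinstance(items[0], Track):
        kins, _ = analyze_tracks(items)
    else:
        kins = items  # type: ignore[assignment]
    if not kins:
        raise ValueError("no revolving cells: nothing to model")
    pop = summarize_population(kins)
    R_m = pop.mean_R * 1e-6
    sol = solve_monoflagellate(R_m, pop.mean_omega, geom, fluid)
    predict_biflagellate_velocity(sol, geom, fluid)
    report = {
        "population": {
            "n_cells": pop.n_cells,
            "mean_R_um": pop.mean_R,
            "mean_omega_rad_s": pop.mean_omega,
        },
        "geometry": {"r_m": geom.r, "alpha_deg": math.degrees(geom.alpha)},
        "fluid": {"eta_Pa_s": fluid.eta},
        "force_solution": _solution_report(sol),
        "energy_balance_residual": energy_balance_residual(
            sol, R_m, pop.mean_omega, geom, fluid),
    }
    if provenance:
        report["provenance"] = provenance
    return report
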