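"""Brute-force verifiers for the closed forms.

Each oracle recomputes a quantity from the governing relations without
using the closed form it guards: the flux law is checked by adaptive
quadrature of the velocity profile, the wall shear stress by
Richardson-extrapolated finite differences of the velocity, and the
Casson constitutive law by residuals of sqrt(tau) = sqrt(tau0) +
sqrt(mu * (-du/dr)) with the stress field tau = drive * r / 2 from the
momentum balance.  They run in the test suite and behind the ``verify``
CLI command; any regression fixture in the package was recorded only
after these verifiers agreed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad

from .casson_station import (
    ForceField,
    _yielded_velocity,
    axial_velocity,
    conductance,
    plug_velocity,
    wall_shear_stress,
)
from .exceptions import InvalidStepError, PlugOverflowError
from .vessel_geometry import VesselGeometry
from . import axial_assembly

__all__ = [
    "OracleReport",
    "DEFAULT_H_GRID",
    "DEFAULT_R0_GRID",
    "DEFAULT_DRIVE_GRID",
    "flux_by_quadrature",
    "check_flux_grid",
    "wss_by_finite_difference",
    "check_wss_grid",
    "casson_residual",
    "check_casson_grid",
    "limit_suite",
]

# Stenosed, normal, and dilated stations at caption-scale parameters.
DEFAULT_H_GRID = (0.7, 0.85, 1.0, 1.1)
DEFAULT_R0_GRID = (0.0, 0.1, 0.2, 0.3)
DEFAULT_DRIVE_GRID = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class OracleReport:
    """Outcome of one verifier over its parameter grid."""

    name: str
    max_abs_error: float
    max_rel_error: float
    grid: str
    tolerance: float
    passed: bool

    @staticmethod
    def from_errors(
        name: str, abs_err: float, rel_err: float, grid: str, tolerance: float,
        use_abs: bool = False,
    ) -> "OracleReport":
        err = abs_err if use_abs else rel_err
        return OracleReport(
            name=name,
            max_abs_error=float(abs_err),
            max_rel_error=float(rel_err),
            grid=grid,
            tolerance=tolerance,
            passed=bool(err <= tolerance),
        )


def flux_by_quadrature(H: float, r0: float, drive: float) -> float:
    """Flux 2*int_0^r0 u_p r dr + 2*int_r0^H u r dr by adaptive quadrature."""
    if r0 > H:
        raise PlugOverflowError(f"plug radius {r0} exceeds lumen radius {H}")
    if r0 == H:
        return 0.0
    plug_part = plug_velocity(H, r0, drive) * r0**2  # 2 * u_p * r0^2 / 2
    annulus, err = quad(
        lambda r: axial_velocity(r, H, r0, drive) * r,
        r0,
        H,
        epsabs=1e-13,
        epsrel=1e-12,
        limit=200,
    )
    return plug_part + 2.0 * annulus


def check_flux_grid(
    H_grid: Sequence[float] = DEFAULT_H_GRID,
    r0_grid: Sequence[float] = DEFAULT_R0_GRID,
    drive_grid: Sequence[float] = DEFAULT_DRIVE_GRID,
    tolerance: float = 1e-8,
    conductance_fn: Callable[[float, float], float] = conductance,
) -> OracleReport:
    """Compare quadrature flux with conductance * drive over the full grid.

    ``conductance_fn`` is the comparison target; injecting a corrupted
    closed form must make this check fail (mutation test hook).
    """
    max_abs = max_rel = 0.0
    for H in H_grid:
        for r0 in r0_grid:
            for D in drive_grid:
                q_ref = flux_by_quadrature(H, r0, D)
                q_cf = conductance_fn(H, r0) * D
                a = abs(q_cf - q_ref)
                max_abs = max(max_abs, a)
                if q_ref != 0:
                    max_rel = max(max_rel, a / abs(q_ref))
    grid = f"H in {tuple(H_grid)}, r0 in {tuple(r0_grid)}, drive in {tuple(drive_grid)}"
    return OracleReport.from_errors("flux_by_quadrature", max_abs, max_rel, grid, tolerance)


def _wall_slope_fd(H: float, r0: float, drive: float, step: float) -> float:
    """du/dr at r = H: one-sided second-order stencil, Richardson-extrapolated.

    Uses the analytic sheared-annulus branch so the stencil may not cross
    into the plug; the closed-form shear expression is never consulted.
    """

    def one_sided(h: float) -> float:
        u0 = _yielded_velocity(H, H, r0, drive)
        u1 = _yielded_velocity(H - h, H, r0, drive)
        u2 = _yielded_velocity(H - 2 * h, H, r0, drive)
        return (3.0 * u0 - 4.0 * u1 + u2) / (2.0 * h)

    d_h = one_sided(step)
    d_h2 = one_sided(step / 2.0)
    return (4.0 * d_h2 - d_h) / 3.0


def wss_by_finite_difference(
    Q: float,
    H: float,
    r0: float,
    force: ForceField,
    mode: str = "derived",
    step: float = 1e-3,
) -> float:
    """Wall shear stress as -mu du/dr at r = H from the velocity profile.

    The drive is reconstructed from the flux as D = Q / g (the inversion
    that eliminates the drive from the flux law).  The result equals the
    derived-mode closed form directly; the paper-mode closed form equals
    it plus the additive body-force term M + f, which is added here when
    ``mode="paper"`` so both modes compare like for like.
    """
    if step >= (H - r0) / 4.0:
        raise InvalidStepError(
            f"step {step} too large for yielded annulus of width {H - r0}"
        )
    g = conductance(H, r0)
    D = Q / g
    tau_viscous = -_wall_slope_fd(H, r0, D, step)
    return tau_viscous + (force.body_force if mode == "paper" else 0.0)


def check_wss_grid(
    Q: float = 0.1,
    H_grid: Sequence[float] = DEFAULT_H_GRID,
    r0_grid: Sequence[float] = DEFAULT_R0_GRID,
    force: ForceField | None = None,
    tolerance: float = 1e-6,
) -> OracleReport:
    """Derived-mode closed-form wall shear vs finite difference."""
    force = force or ForceField()
    max_abs = max_rel = 0.0
    for H in H_grid:
        for r0 in r0_grid:
            ref = wss_by_finite_difference(Q, H, r0, force, "derived")
            cf = wall_shear_stress(Q, H, r0, force, "derived")
            a = abs(cf - ref)
            max_abs = max(max_abs, a)
            if ref != 0:
                max_rel = max(max_rel, a / abs(ref))
    grid = f"H in {tuple(H_grid)}, r0 in {tuple(r0_grid)}, Q={Q}"
    return OracleReport.from_errors("wss_by_finite_difference", max_abs, max_rel, grid, tolerance)


def casson_residual(
    r_grid,
    H: float,
    r0: float,
    drive: float,
    fd_step: float | None = None,
) -> float:
    """Max residual of the Casson law sqrt(tau) = sqrt(tau0) + sqrt(-mu du/dr).

    The stress field is tau = drive * r / 2 from the momentum balance and
    tau0 = drive * r0 / 2 from the plug force balance; du/dr comes from a
    Richardson-extrapolated central difference of the velocity profile.
    """
    r_arr = np.asarray(r_grid, dtype=float)
    if np.any(r_arr <= r0) or np.any(r_arr > H):
        raise InvalidStepError("residual grid must lie within (r0, H]")
    h = fd_step if fd_step is not None else 1e-3 * max(H - r0, 1e-3)

    def slope(r: float) -> float:
        def central(hh: float) -> float:
            return (
                _yielded_velocity(r + hh, H, r0, drive)
                - _yielded_velocity(r - hh, H, r0, drive)
            ) / (2.0 * hh)

        return (4.0 * central(h / 2.0) - central(h)) / 3.0

    tau0 = drive * r0 / 2.0
    worst = 0.0
    for r in r_arr:
        tau = drive * r / 2.0
        shear_rate = -slope(float(r))
        res = abs(math.sqrt(tau) - math.sqrt(tau0) - math.sqrt(max(shear_rate, 0.0)))
        worst = max(worst, res)
    return worst


def check_casson_grid(
    H_grid: Sequence[float] = DEFAULT_H_GRID,
    r0_grid: Sequence[float] = DEFAULT_R0_GRID,
    drive_grid: Sequence[float] = DEFAULT_DRIVE_GRID,
    tolerance: float = 1e-8,
    points: int = 9,
) -> OracleReport:
    """Constitutive residual over the oracle grid (absolute tolerance)."""
    worst = 0.0
    for H in H_grid:
        for r0 in r0_grid:
            for D in drive_grid:
                lo = r0 + 0.05 * (H - r0)
                grid = np.linspace(lo, H, points)
                worst = max(worst, casson_residual(grid, H, r0, D))
    desc = f"H in {tuple(H_grid)}, r0 in {tuple(r0_grid)}, drive in {tuple(drive_grid)}"
    return OracleReport.from_errors(
        "casson_residual", worst, worst, desc, tolerance, use_abs=True
    )


def limit_suite(force: ForceField | None = None, Q: float = 0.1) -> list[OracleReport]:
    """All degenerate-limit identities in one pass.

    Newtonian limit (r0 = 0): Poiseuille profile, g = H^4/8, tau_w = 4Q/H^3;
    plug-degenerate limit (r0 = H): zero velocity and flux; no-slip at every
    station; lesion-free normalization lambda_bar = tau_bar_w = 1 in both
    sign conventions.
    """
    force = force or ForceField()
    reports: list[OracleReport] = []

    # Newtonian collapse: profile, conductance, wall shear simultaneously.
    worst = 0.0
    for H in DEFAULT_H_GRID:
        r = np.linspace(0.0, H, 21)
        u = axial_velocity(r, H, 0.0, 1.0)
        worst = max(worst, float(np.max(np.abs(u - 0.25 * (H**2 - r**2)))))
        worst = max(worst, abs(conductance(H, 0.0) - H**4 / 8.0))
        tau = wall_shear_stress(Q, H, 0.0, force, "derived")
        worst = max(worst, abs(tau - 4.0 * Q / H**3))
    reports.append(
        OracleReport.from_errors(
            "newtonian_collapse", worst, worst, f"H in {DEFAULT_H_GRID}", 1e-12, use_abs=True
        )
    )

    # Plug-degenerate limit r0 = H: plug speed and flux vanish.
    worst = 0.0
    for H in DEFAULT_H_GRID:
        worst = max(worst, abs(plug_velocity(H, H, 1.0)))
        worst = max(worst, abs(flux_by_quadrature(H, H, 1.0)))
    reports.append(
        OracleReport.from_errors(
            "plug_degenerate", worst, worst, f"H in {DEFAULT_H_GRID}", 1e-12, use_abs=True
        )
    )

    # No-slip at the wall for every (H, r0) pair.
    worst = 0.0
    for H in DEFAULT_H_GRID:
        for r0 in DEFAULT_R0_GRID:
            worst = max(worst, abs(axial_velocity(H, H, r0, 1.7)))
    reports.append(
        OracleReport.from_errors(
            "no_slip", worst, worst,
            f"H in {DEFAULT_H_GRID}, r0 in {DEFAULT_R0_GRID}", 1e-12, use_abs=True,
        )
    )

    # Lesion-free normalization identities in both modes.
    worst = 0.0
    empty = VesselGeometry()
    for mode in ("paper", "derived"):
        lam_bar = axial_assembly.normalized_impedance(Q, empty, 0.2, force, mode)
        tau_bar = axial_assembly.normalized_wss(Q, empty, 0.2, force, mode, station=0.5)
        worst = max(worst, abs(lam_bar - 1.0), abs(tau_bar - 1.0))
    reports.append(
        OracleReport.from_errors(
            "lesion_free_normalization", worst, worst, "empty geometry, both modes",
            1e-12, use_abs=True,
        )
    )
    return reports
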