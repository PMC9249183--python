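"""Axial integration: pressure drop, impedance, and normalized quantities.

The station solution holds at every z with the local wall radius H(z).
Integrating the pressure gradient along the tube gives the pressure drop
``delta_p = int_0^L P(z) dz``; impedance is ``lambda = delta_p / Q`` and is
normalized by the uniform-tube value ``lambda_n`` computed with H = 1 over
the *same* domain length.  The wall shear stress is normalized likewise by
its H = 1 value ``tau_wn``, and reported at a chosen station (by default
the throat: the first abnormal segment's midpoint).

Quadrature is composite Simpson on panels aligned with segment boundaries,
because H(z) has derivative kinks at each alpha_i / beta_i while being
smooth inside every panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import simpson

from .casson_station import ForceField, conductance, wall_shear_stress, _check_mode
from .exceptions import (
    GeometryError,
    NormalizationError,
    PlugOverflowError,
    UndefinedImpedanceError,
)
from .vessel_geometry import VesselGeometry, wall_radius

__all__ = [
    "AxialSolution",
    "pressure_drop",
    "impedance",
    "reference_impedance",
    "normalized_impedance",
    "reference_wss",
    "normalized_wss",
    "wss_profile",
    "solve",
]

DEFAULT_QUADRATURE_POINTS = 2001


def _panel_grids(geometry: VesselGeometry, n_points: int) -> list[np.ndarray]:
    """Per-panel Simpson grids between 0, each alpha_i/beta_i inside the domain, L.

    Nodes are distributed proportionally to panel length, with an even
    number (>= 2) of intervals per panel so Simpson's rule applies cleanly.
    """
    L = geometry.length
    cuts = {0.0, L}
    for b in geometry.bounds:
        for x in (b.alpha, b.beta):
            if 0.0 < x < L:
                cuts.add(float(x))
    edges = sorted(cuts)
    grids = []
    for a, b in zip(edges[:-1], edges[1:]):
        m = int(round(max(n_points - 1, 4) * (b - a) / L))
        m = max(2, (m // 2) * 2)  # even, at least 2 intervals
        grids.append(np.linspace(a, b, m + 1))
    return grids


def _station_pressure_gradient(z, Q, geometry, r0, force, mode):
    H = np.asarray(wall_radius(z, geometry), dtype=float)
    if np.any(H <= r0):
        worst = float(np.asarray(z, dtype=float)[np.argmin(H)]) if np.ndim(z) else float(z)
        raise PlugOverflowError(
            f"plug radius {r0} reaches the lumen (H = {H.min():.6g}) near z = {worst:.6g}"
        )
    g = conductance(H, r0)
    bf = force.body_force
    return (-Q / g + bf) if mode == "paper" else (Q / g - bf)


def pressure_drop(
    Q: float,
    geometry: VesselGeometry,
    r0: float,
    force: ForceField,
    mode: str = "paper",
    quadrature_points: int = DEFAULT_QUADRATURE_POINTS,
) -> float:
    """Axial integral of the pressure gradient over the whole domain."""
    _check_mode(mode)
    total = 0.0
    for z in _panel_grids(geometry, quadrature_points):
        P = _station_pressure_gradient(z, Q, geometry, r0, force, mode)
        total += simpson(P, x=z)
    return float(total)


def impedance(
    Q: float,
    geometry: VesselGeometry,
    r0: float,
    force: ForceField,
    mode: str = "paper",
    quadrature_points: int = DEFAULT_QUADRATURE_POINTS,
) -> float:
    """Flow resistance lambda = delta_p / Q."""
    if Q == 0:
        raise UndefinedImpedanceError("impedance is undefined at zero flux")
    return pressure_drop(Q, geometry, r0, force, mode, quadrature_points) / Q


def reference_impedance(
    Q: float,
    r0: float,
    force: ForceField,
    mode: str = "paper",
    domain_length: float = 1.0,
) -> float:
    """Uniform-tube (H = 1) impedance over the same domain length.

    The integrand is constant, so the integral is closed-form.
    """
    _check_mode(mode)
    if Q == 0:
        raise UndefinedImpedanceError("impedance is undefined at zero flux")
    g = conductance(1.0, r0)
    bf = force.body_force
    P = (-Q / g + bf) if mode == "paper" else (Q / g - bf)
    return P * domain_length / Q


def normalized_impedance(
    Q: float,
    geometry: VesselGeometry,
    r0: float,
    force: ForceField,
    mode: str = "paper",
    quadrature_points: int = DEFAULT_QUADRATURE_POINTS,
) -> float:
    """lambda_bar = lambda / lambda_n; equals 1 exactly for a lesion-free tube."""
    lam_n = reference_impedance(Q, r0, force, mode, geometry.length)
    if lam_n == 0:
        raise NormalizationError("reference impedance is zero; lambda_bar undefined")
    return impedance(Q, geometry, r0, force, mode, quadrature_points) / lam_n


def reference_wss(Q: float, r0: float, force: ForceField, mode: str = "paper") -> float:
    """Uniform-tube (H = 1) wall shear stress tau_wn."""
    return wall_shear_stress(Q, 1.0, r0, force, mode)


def normalized_wss(
    Q: float,
    geometry: VesselGeometry,
    r0: float,
    force: ForceField,
    mode: str = "paper",
    station: float | str = "throat",
) -> float:
    """tau_bar_w = tau_w(z*) / tau_wn at the requested station.

    ``station="throat"`` resolves to the first abnormal segment's midpoint;
    it is an error for a lesion-free geometry (pass an explicit z instead).
    """
    if station == "throat":
        z_star = geometry.throat()
    else:
        z_star = float(station)
    H = wall_radius(z_star, geometry)
    tau_n = reference_wss(Q, r0, force, mode)
    if tau_n == 0:
        raise NormalizationError("reference wall shear stress is zero; tau_bar_w undefined")
    return wall_shear_stress(Q, H, r0, force, mode) / tau_n


def wss_profile(
    z_grid,
    Q: float,
    geometry: VesselGeometry,
    r0: float,
    force: ForceField,
    mode: str = "paper",
) -> pd.DataFrame:
    """Per-station table (z, H, P, tau_w) along an axial grid."""
    z = np.asarray(z_grid, dtype=float)
    H = np.asarray(wall_radius(z, geometry), dtype=float)
    P = _station_pressure_gradient(z, Q, geometry, r0, force, mode)
    tau = np.array([wall_shear_stress(Q, h, r0, force, mode) for h in H])
    return pd.DataFrame({"z": z, "H": H, "P": P, "tau_w": tau})


@dataclass(frozen=True)
class AxialSolution:
    """Integrated axial quantities for one parameter set."""

    pressure_drop: float
    impedance: float
    reference_impedance: float
    normalized_impedance: float
    reference_wss: float
    normalized_wss: float
    evaluation_station: float
    wall_shear_profile: pd.DataFrame

    @property
    def abs_pressure_drop(self) -> float:
        """Magnitude convenience for plotting parity with sign-free figures."""
        return abs(self.pressure_drop)


def solve(
    Q: float,
    geometry: VesselGeometry,
    r0: float,
    force: ForceField,
    mode: str = "paper",
    quadrature_points: int = DEFAULT_QUADRATURE_POINTS,
    station: float | str = "throat",
    profile_points: int = 201,
) -> AxialSolution:
    """Full axial assembly: delta_p, lambda, lambda_n, lambda_bar, tau profiles."""
    if r0 >= geometry.min_radius():
        raise PlugOverflowError(
            f"plug radius {r0} reaches the narrowest lumen radius {geometry.min_radius()}"
        )
    if Q == 0:
        raise UndefinedImpedanceError("impedance is undefined at zero flux")
    dp = pressure_drop(Q, geometry, r0, force, mode, quadrature_points)
    lam = dp / Q
    lam_n = reference_impedance(Q, r0, force, mode, geometry.length)
    if lam_n == 0:
        raise NormalizationError("reference impedance is zero")
    z_star = geometry.throat() if station == "throat" else float(station)
    z_grid = np.linspace(0.0, geometry.length, profile_points)
    return AxialSolution(
        pressure_drop=dp,
        impedance=lam,
        reference_impedance=lam_n,
        normalized_impedance=lam / lam_n,
        reference_wss=reference_wss(Q, r0, force, mode),
        normalized_wss=normalized_wss(Q, geometry, r0, force, mode, z_star),
        evaluation_station=z_star,
        wall_shear_profile=wss_profile(z_grid, Q, geometry, r0, force, mode),
    )
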