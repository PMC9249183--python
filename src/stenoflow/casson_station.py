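"""Per-axial-station Casson flow solution.

At each axial station the tube looks locally uniform (mild-lesion
approximation) with wall radius ``H``.  Steady, fully developed Casson
flow under a net axial drive ``D = M + f + P`` (magnetization constant
``M``, gravity term ``f = F sin(phi)``, pressure gradient ``P``; dynamic
viscosity ``mu = 1`` in dimensionless form) then has the classical
yield-stress structure: an unyielded plug core of radius ``r0`` moving
at uniform speed, surrounded by a sheared annulus.

For ``r0 <= r <= H``::

    u(r) = (D/2) * [ (H^2 - r^2)/2 - (4/3) sqrt(r0) (H^(3/2) - r^(3/2)) + r0 (H - r) ]

with ``u = u(r0)`` on the plug and ``u(H) = 0`` (no slip).  Integrating
``2 * int u r dr`` gives the Buckingham-Reiner-type flux law ``Q = g * D``
with conductance::

    g(H, r0) = H^3 r0 / 6 + H^4 / 8 - r0^4 / 168 - (2/7) sqrt(r0) H^(7/2)

Two sign conventions for inverting the flux law are shipped:

``"paper"`` (default)
    ``P = -Q/g + (M + f)`` and ``tau_w = (Q/2g)(sqrt(H)-sqrt(r0))^2 + (M + f)``,
    the printed forms that the source figures' parameter trends follow.
``"derived"``
    ``P = Q/g - (M + f)``, the algebraically self-consistent inversion of
    ``Q = g (M + f + P)``; ``tau_w = (Q/2g)(sqrt(H)-sqrt(r0))^2`` is then
    exactly ``-mu du/dr`` at the wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import (
    DegenerateStationError,
    DomainError,
    NoFlowError,
    PlugOverflowError,
    ValidationError,
)

__all__ = [
    "CassonParameters",
    "ForceField",
    "StationSolution",
    "conductance",
    "axial_velocity",
    "plug_velocity",
    "pressure_gradient",
    "wall_shear_stress",
    "plug_radius_from_yield",
    "drive",
    "solve_station",
    "MODES",
]

MODES = ("paper", "derived")


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")


@dataclass(frozen=True)
class CassonParameters:
    """Rheology inputs: the plug-core radius, optionally a yield stress.

    ``plug_radius`` (r0) is the free dimensionless sweep variable; it must
    stay below the narrowest lumen radius it is used with.  ``yield_stress``
    is an optional dimensional-prelude quantity related to r0 through the
    plug force balance ``P r0 / 2 = tau_0``.
    """

    plug_radius: float = 0.2
    yield_stress: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.plug_radius < 1:
            raise ValidationError(f"plug_radius must lie in [0, 1), got {self.plug_radius}")
        if self.yield_stress is not None and self.yield_stress < 0:
            raise ValidationError("yield_stress must be >= 0")


@dataclass(frozen=True)
class ForceField:
    """Constant body-force field: magnetization M, gravity F, inclination phi.

    The axial gravity component is ``f = F sin(phi)`` (zero for a horizontal
    tube or F = 0); ``body_force = M + f`` is the flux-independent part of
    the drive.
    """

    magnetization: float = 2.0
    gravity: float = 0.3
    inclination: float = math.pi / 6

    @property
    def axial_gravity(self) -> float:
        return self.gravity * math.sin(self.inclination)

    @property
    def body_force(self) -> float:
        return self.magnetization + self.axial_gravity


def conductance(H, r0: float):
    """Flux per unit drive, ``Q = g(H, r0) * (M + f + P)``.

    ``H`` may be a scalar or array of station radii; ``r0`` is scalar.
    Positive for ``r0 < H``; exactly zero at the degenerate ``r0 = H``.
    """
    H_arr = np.asarray(H, dtype=float)
    if r0 < 0:
        raise ValidationError(f"plug radius must be >= 0, got {r0}")
    if np.any(r0 > H_arr):
        raise PlugOverflowError(
            f"plug radius {r0} exceeds the lumen radius (min H = {H_arr.min()})"
        )
    g = (
        H_arr**3 * r0 / 6.0
        + H_arr**4 / 8.0
        - r0**4 / 168.0
        - (2.0 / 7.0) * math.sqrt(r0) * H_arr**3.5
    )
    return float(g) if np.ndim(H) == 0 else g


def _yielded_velocity(r, H: float, r0: float, drive: float):
    """Sheared-annulus closed form, valid for r >= r0; no range checks.

    Exposed for the brute-force oracles, which need to evaluate the smooth
    analytic branch on finite-difference stencils straddling r = H.
    """
    r_arr = np.asarray(r, dtype=float)
    s = math.sqrt(r0)
    return (drive / 2.0) * (
        0.5 * (H**2 - r_arr**2)
        - (4.0 / 3.0) * s * (H**1.5 - r_arr**1.5)
        + r0 * (H - r_arr)
    )


def plug_velocity(H: float, r0: float, drive: float) -> float:
    """Uniform speed of the unyielded core (the sheared form at r = r0)."""
    if r0 > H:
        raise PlugOverflowError(f"plug radius {r0} exceeds lumen radius {H}")
    s = math.sqrt(r0)
    return (drive / 2.0) * (
        0.5 * H**2 + H * r0 - (4.0 / 3.0) * s * H**1.5 - r0**2 / 6.0
    )


def axial_velocity(r, H: float, r0: float, drive: float):
    """Velocity profile u(r) on [0, H]: flat plug core, sheared annulus, no slip."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > H):
        raise DomainError(f"r must lie within [0, {H}]")
    if r0 > H:
        raise PlugOverflowError(f"plug radius {r0} exceeds lumen radius {H}")
    u = _yielded_velocity(r_arr, H, r0, drive)
    if r0 > 0:
        u = np.where(r_arr < r0, plug_velocity(H, r0, drive), u)
    return float(u) if np.ndim(r) == 0 else u


def pressure_gradient(
    Q: float, H: float, r0: float, force: ForceField, mode: str = "paper"
) -> float:
    """Invert the flux law for the axial pressure gradient P at one station."""
    _check_mode(mode)
    g = conductance(H, r0)
    if r0 >= H or g <= 0.0:
        raise DegenerateStationError(
            f"conductance vanished at H={H}, r0={r0}; pressure gradient undefined"
        )
    if mode == "paper":
        return -Q / g + force.body_force
    return Q / g - force.body_force


def drive(Q: float, H: float, r0: float, force: ForceField, mode: str = "paper") -> float:
    """Net axial forcing D = M + f + P for the chosen inversion mode.

    ``derived``: D = Q/g exactly. ``paper``: D = 2(M + f) - Q/g, the drive
    implied by the printed pressure-gradient form.
    """
    return force.body_force + pressure_gradient(Q, H, r0, force, mode)


def wall_shear_stress(
    Q: float, H: float, r0: float, force: ForceField, mode: str = "paper"
) -> float:
    """Wall shear stress tau_w at one station.

    The viscous part is ``(Q / 2g) (sqrt(H) - sqrt(r0))^2``; paper mode adds
    the body-force term ``M + f`` carried by the printed formula.
    """
    _check_mode(mode)
    g = conductance(H, r0)
    if r0 >= H or g <= 0.0:
        raise DegenerateStationError(f"conductance vanished at H={H}, r0={r0}")
    viscous = Q * (math.sqrt(H) - math.sqrt(r0)) ** 2 / (2.0 * g)
    if mode == "paper":
        return viscous + force.body_force
    return viscous


def plug_radius_from_yield(
    tau0: float, P: float, lumen_radius: float | None = None
) -> float:
    """Plug radius from the core force balance ``P r0 / 2 = tau_0``.

    Raises :class:`NoFlowError` when ``P = 0`` with a finite yield stress
    (the whole cross-section is unyielded) and :class:`PlugOverflowError`
    if the resulting core would not fit inside ``lumen_radius``.
    """
    if tau0 < 0:
        raise ValidationError("yield stress must be >= 0")
    if tau0 == 0:
        return 0.0
    if P == 0:
        raise NoFlowError("zero pressure gradient with finite yield stress: no flow")
    r0 = 2.0 * tau0 / abs(P)
    if lumen_radius is not None and r0 >= lumen_radius:
        raise PlugOverflowError(
            f"plug radius {r0} from tau0={tau0}, P={P} reaches the lumen radius {lumen_radius}"
        )
    return r0


@dataclass(frozen=True)
class StationSolution:
    """Everything known about the flow at one axial station."""

    wall_radius: float
    plug_radius: float
    pressure_gradient: float
    drive: float
    plug_velocity: float
    wall_shear: float
    velocity: Callable[[float], float]


def solve_station(
    H: float,
    Q: float,
    r0: float,
    force: ForceField,
    mode: str = "paper",
) -> StationSolution:
    """Assemble the full per-station solution for flux Q at wall radius H."""
    P = pressure_gradient(Q, H, r0, force, mode)
    D = force.body_force + P
    return StationSolution(
        wall_radius=H,
        plug_radius=r0,
        pressure_gradient=P,
        drive=D,
        plug_velocity=plug_velocity(H, r0, D),
        wall_shear=wall_shear_stress(Q, H, r0, force, mode),
        velocity=lambda r: axial_velocity(r, H, r0, D),
    )
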