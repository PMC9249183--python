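"""Multi-segment vessel wall geometry.

The vessel is an axisymmetric tube of dimensionless reference radius
``R0 = 1`` whose wall carries a sequence of cosine-shaped abnormal
segments: stenoses (positive height, lumen narrowing) and post-stenotic
dilatations (negative height, lumen widening).  Inside segment *i*,
spanning ``[alpha_i, beta_i]`` along the axis, the wall radius is

    H(z) = R0 - (delta_i / 2) * [1 + cos(2*pi*(z - alpha_i - L_i/2) / L_i)]

and ``H(z) = R0`` elsewhere.  The bump vanishes at both segment ends, so
the profile is continuous, and attains its full height ``R0 - delta_i``
at the segment midpoint (the *throat* for a stenosis).

Segment placement follows partial sums: with ``d_i`` the gap from the end
of the previous segment (or the inlet) to the start of segment *i*,

    alpha_i = -L_i + sum_{j<=i} (L_j + d_j),      beta_i = sum_{j<=i} (L_j + d_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DomainError, GeometryError, ValidationError

__all__ = [
    "AbnormalSegment",
    "SegmentBounds",
    "VesselGeometry",
    "MildStenosisReport",
    "segment_bounds",
    "wall_radius",
    "wall_profile",
    "validate_mild_stenosis",
]


@dataclass(frozen=True)
class AbnormalSegment:
    """One cosine-shaped wall lesion.

    Parameters
    ----------
    delta : float
        Signed dimensionless lesion height (fraction of ``R0``):
        positive for a stenosis, negative for a dilatation. ``|delta| < 1``.
    length : float
        Dimensionless axial extent ``L_i`` of the lesion, > 0.
    gap : float
        Dimensionless distance ``d_i`` from the end of the previous
        segment (or the tube inlet) to this segment's start, >= 0.
    """

    delta: float
    length: float
    gap: float

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValidationError(f"segment length must be > 0, got {self.length}")
        if self.gap < 0:
            raise ValidationError(f"segment gap must be >= 0, got {self.gap}")
        if not abs(self.delta) < 1:
            raise GeometryError(
                f"|delta| must be < 1 to keep the wall radius positive, got {self.delta}"
            )

    @classmethod
    def stenosis(cls, height: float, length: float, gap: float) -> "AbnormalSegment":
        """Narrowing lesion from a positive height magnitude."""
        if height < 0:
            raise ValidationError("stenosis height must be a non-negative magnitude")
        return cls(delta=height, length=length, gap=gap)

    @classmethod
    def dilatation(cls, height: float, length: float, gap: float) -> "AbnormalSegment":
        """Widening lesion (aneurysm-like bulge) from a positive height magnitude."""
        if height < 0:
            raise ValidationError("dilatation height must be a non-negative magnitude")
        return cls(delta=-height, length=length, gap=gap)

    @classmethod
    def from_kind(cls, kind: str, height: float, length: float, gap: float) -> "AbnormalSegment":
        if kind == "stenosis":
            return cls.stenosis(height, length, gap)
        if kind == "dilatation":
            return cls.dilatation(height, length, gap)
        raise ValidationError(f"unknown segment kind {kind!r} (expected stenosis|dilatation)")

    @property
    def kind(self) -> str:
        return "dilatation" if self.delta < 0 else "stenosis"


@dataclass(frozen=True)
class SegmentBounds:
    """Axial start/end coordinates ``(alpha_i, beta_i)`` of one segment."""

    alpha: float
    beta: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.alpha + self.beta)


@dataclass(frozen=True)
class VesselGeometry:
    """Ordered abnormal segments plus the axial domain they live in.

    ``domain_length=None`` (the default, "auto") resolves to
    ``max(1, beta_last)`` so that no lesion is truncated mid-bump while a
    lesion-free tube keeps unit length.  An explicit value is honoured
    as given (it may deliberately truncate the domain).
    """

    segments: tuple[AbnormalSegment, ...] = ()
    reference_radius: float = 1.0
    domain_length: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.reference_radius > 0:
            raise GeometryError("reference_radius must be > 0")
        if self.domain_length is not None and not self.domain_length > 0:
            raise ValidationError("explicit domain_length must be > 0")

    @property
    def bounds(self) -> tuple[SegmentBounds, ...]:
        return segment_bounds(self)

    @property
    def length(self) -> float:
        """Resolved axial domain length."""
        if self.domain_length is not None:
            return float(self.domain_length)
        b = self.bounds
        return max(1.0, b[-1].beta) if b else 1.0

    def throat(self, index: int = 0) -> float:
        """Midpoint of the ``index``-th abnormal segment."""
        b = self.bounds
        if not b:
            raise GeometryError("geometry has no abnormal segment; no throat exists")
        return b[index].midpoint

    def min_radius(self) -> float:
        """Exact minimum of H over the domain (attained at a segment midpoint or R0)."""
        r = self.reference_radius
        for seg, b in zip(self.segments, self.bounds):
            if b.alpha <= self.length:  # segment at least partially inside the domain
                r = min(r, self.reference_radius - seg.delta)
        return r


def segment_bounds(geometry: VesselGeometry) -> tuple[SegmentBounds, ...]:
    """Start/end coordinates of each segment via cumulative lengths and gaps."""
    out: list[SegmentBounds] = []
    run = 0.0
    for i, seg in enumerate(geometry.segments):
        if not seg.length > 0:
            raise ValidationError(f"segment {i} has non-positive length {seg.length}")
        if seg.gap < 0:
            raise ValidationError(f"segment {i} has negative gap {seg.gap}")
        run += seg.length + seg.gap
        out.append(SegmentBounds(alpha=run - seg.length, beta=run))
    return tuple(out)


def wall_radius(z, geometry: VesselGeometry):
    """Dimensionless wall radius ``H(z)``.

    Accepts a scalar or array ``z`` within ``[0, domain_length]``.  At a
    shared segment boundary both cosine bumps vanish, so inclusive masks
    are unambiguous.
    """
    z_arr = np.asarray(z, dtype=float)
    L = geometry.length
    if np.any(z_arr < 0) or np.any(z_arr > L):
        raise DomainError(f"z must lie within [0, {L}]")
    H = np.full(z_arr.shape, geometry.reference_radius, dtype=float)
    for seg, b in zip(geometry.segments, geometry.bounds):
        m = (z_arr >= b.alpha) & (z_arr <= b.beta)
        if np.any(m):
            arg = 2.0 * np.pi * (z_arr[m] - b.alpha - seg.length / 2.0) / seg.length
            H[m] -= seg.delta / 2.0 * (1.0 + np.cos(arg))
    if np.any(H <= 0):
        raise GeometryError("wall radius is non-positive; |delta| must stay below R0")
    return float(H) if np.isscalar(z) or np.ndim(z) == 0 else H


def wall_profile(z_grid, geometry: VesselGeometry) -> np.ndarray:
    """Vectorized wall radius on an increasing axial grid."""
    z_arr = np.asarray(z_grid, dtype=float)
    if z_arr.ndim != 1 or z_arr.size == 0:
        raise ValidationError("z_grid must be a non-empty 1-D sequence")
    if z_arr.size > 1 and not np.all(np.diff(z_arr) > 0):
        raise ValidationError("z_grid must be strictly increasing")
    return np.asarray(wall_radius(z_arr, geometry), dtype=float)


@dataclass(frozen=True)
class MildStenosisReport:
    """Advisory report on the mild-lesion regime.

    The closed-form station solution assumes each lesion is shallow
    relative to both its own length and the vessel radius:
    ``|delta_i| << L_i`` and ``|delta_i| << min(R0, R_out)`` with
    ``R_out = R0`` in dimensionless form.  "<<" is operationalized as
    ratio <= tolerance.
    """

    tolerance: float
    height_to_length: tuple[float, ...]
    height_to_radius: tuple[float, ...]
    flagged: tuple[int, ...]

    @property
    def passed(self) -> bool:
        return not self.flagged


def validate_mild_stenosis(
    geometry: VesselGeometry, tolerance: float = 0.3, strict: bool = False
) -> MildStenosisReport:
    """Check each segment against the mild-lesion ratios; advisory by default.

    With ``strict=True`` a violation raises :class:`GeometryError` instead
    of merely flagging the segment.
    """
    r_ref = min(geometry.reference_radius, geometry.reference_radius)  # R_out = R0
    htl = tuple(abs(s.delta) / s.length for s in geometry.segments)
    htr = tuple(abs(s.delta) / r_ref for s in geometry.segments)
    flagged = tuple(
        i for i, (a, b) in enumerate(zip(htl, htr)) if a > tolerance or b > tolerance
    )
    report = MildStenosisReport(
        tolerance=tolerance, height_to_length=htl, height_to_radius=htr, flagged=flagged
    )
    if strict and flagged:
        raise GeometryError(
            f"segments {list(flagged)} violate the mild-lesion ratios at tolerance {tolerance}"
        )
    return report
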