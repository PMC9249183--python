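"""Model configuration: schema, YAML/JSON loading, caption defaults.

A config file looks like::

    geometry:
      segments:
        - {kind: stenosis,   height: 0.10, length: 0.2, gap: 0.2}
        - {kind: dilatation, height: 0.10, length: 0.2, gap: 0.6}
      domain_length: auto
    casson:
      plug_radius: 0.2
    forces: {M: 2.0, F: 0.3, phi: 0.5235987755982988}
    flux: 0.1
    mode: paper

Segments take positive height magnitudes with an explicit kind; the sign
of the wall equation is applied internally (stenosis narrows, dilatation
widens), which prevents silent sign mistakes in sweeps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .casson_station import ForceField, MODES, plug_radius_from_yield
from .exceptions import ValidationError
from .vessel_geometry import AbnormalSegment, VesselGeometry

__all__ = ["ModelConfig", "caption_defaults", "parse_config", "load_config", "config_to_dict"]


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameter set for one model evaluation."""

    geometry: VesselGeometry
    plug_radius: float = 0.2
    forces: ForceField = ForceField()
    flux: float = 0.1
    mode: str = "paper"
    quadrature_points: int = 2001
    station: float | str = "throat"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 <= self.plug_radius < 1:
            raise ValidationError(f"plug_radius must lie in [0, 1), got {self.plug_radius}")

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


def caption_defaults(delta1: float = 0.1, delta2: float = 0.1) -> ModelConfig:
    """The anchor parameter set used throughout the reproduced figures.

    Two lesions: a stenosis (height ``delta1``, gap 0.2, length 0.2) and a
    downstream dilatation (height ``delta2``, gap 0.6, length 0.2); plug
    radius 0.2, M = 2.0, F = 0.3, phi = pi/6, flux Q = 0.1.
    """
    segs = []
    if delta1 is not None:
        segs.append(AbnormalSegment.stenosis(delta1, length=0.2, gap=0.2))
    if delta2 is not None:
        segs.append(AbnormalSegment.dilatation(delta2, length=0.2, gap=0.6))
    return ModelConfig(
        geometry=VesselGeometry(segments=tuple(segs)),
        plug_radius=0.2,
        forces=ForceField(magnetization=2.0, gravity=0.3, inclination=math.pi / 6),
        flux=0.1,
        mode="paper",
    )


def parse_config(data: dict) -> ModelConfig:
    """Build a :class:`ModelConfig` from a plain dict (parsed YAML/JSON)."""
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    geo = data.get("geometry", {})
    segments = tuple(
        AbnormalSegment.from_kind(
            s.get("kind", "stenosis"),
            float(s["height"]),
            float(s["length"]),
            float(s["gap"]),
        )
        for s in geo.get("segments", [])
    )
    dl = geo.get("domain_length", "auto")
    domain_length = None if dl in (None, "auto") else float(dl)
    geometry = VesselGeometry(segments=segments, domain_length=domain_length)

    forces_block = data.get("forces", {})
    forces = ForceField(
        magnetization=float(forces_block.get("M", 2.0)),
        gravity=float(forces_block.get("F", 0.3)),
        inclination=float(forces_block.get("phi", math.pi / 6)),
    )

    casson = data.get("casson", {})
    if "plug_radius" in casson:
        r0 = float(casson["plug_radius"])
    elif "yield_stress" in casson:
        # Convert through the plug force balance at the uniform-tube
        # paper-mode zero-flux gradient P = M + f (the only flux-free anchor).
        r0 = plug_radius_from_yield(float(casson["yield_stress"]), forces.body_force)
    else:
        r0 = 0.2

    return ModelConfig(
        geometry=geometry,
        plug_radius=r0,
        forces=forces,
        flux=float(data.get("flux", 0.1)),
        mode=str(data.get("mode", "paper")),
        quadrature_points=int(data.get("quadrature_points", 2001)),
        station=data.get("station", "throat"),
    )


def load_config(path: str | Path) -> ModelConfig:
    """Load a YAML or JSON config file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return parse_config(json.loads(text))
    return parse_config(yaml.safe_load(text))


def config_to_dict(config: ModelConfig) -> dict:
    """Serialize back to the file schema; parse(config_to_dict(c)) == c."""
    return {
        "geometry": {
            "segments": [
                {
                    "kind": s.kind,
                    "height": abs(s.delta),
                    "length": s.length,
                    "gap": s.gap,
                }
                for s in config.geometry.segments
            ],
            "domain_length": (
                "auto" if config.geometry.domain_length is None
                else config.geometry.domain_length
            ),
        },
        "casson": {"plug_radius": config.plug_radius},
        "forces": {
            "M": config.forces.magnetization,
            "F": config.forces.gravity,
            "phi": config.forces.inclination,
        },
        "flux": config.flux,
        "mode": config.mode,
        "quadrature_points": config.quadrature_points,
        "station": config.station,
    }
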