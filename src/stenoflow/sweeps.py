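"""Parameter sweeps, qualitative figure reproduction, trend checking.

The source figures plot normalized impedance (lambda_bar), normalized
wall shear stress (tau_bar_w) and velocity (u) against one swept
parameter, with a second parameter indexing the curve family.  No axis
values are printed in the source, so reproduction is qualitative: the
suite regenerates every sweep as a CSV (plus an optional plot) and a
monotonicity report checks the directions the source states.

Sweep grids (the source prints none): 21-point uniform grids spanning
delta in [0, 0.2], M in [0, 4], phi in [0, pi/2], r0 in [0.01, 0.4],
bracketing every caption value inside the mild-lesion regime.  Exception:
impedance-response sweeps use r0 in [0.15, 0.4] and M in [0, 3], because
the printed sign convention gives the uniform-tube pressure gradient
-Q/g(1, r0) + (M + f) a zero crossing (a pole of lambda_bar) at
r0 ~ 0.118 / M ~ 3.12 under the caption forcing; the restricted grids
keep every curve family on the physical side of that pole.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import axial_assembly
from .casson_station import ForceField, axial_velocity, drive
from .config import ModelConfig, caption_defaults
from .exceptions import PlugOverflowError, StenoflowError, ValidationError
from .vessel_geometry import AbnormalSegment, VesselGeometry, wall_radius

__all__ = [
    "SweepSpec",
    "TrendExpectation",
    "TrendResult",
    "SWEEP_PARAMETERS",
    "DEFAULT_GRIDS",
    "FAMILY_DELTAS",
    "run_sweep",
    "radial_profile_table",
    "monotonicity_report",
    "default_expectations",
    "run_trend_suite",
    "evaluate_trends",
    "figure_suite",
    "FIGURE_SPECS",
]

SWEEP_PARAMETERS = ("delta1", "delta2", "M", "phi", "r0")

DEFAULT_GRIDS: dict[str, np.ndarray] = {
    "delta1": np.linspace(0.0, 0.2, 21),
    "delta2": np.linspace(0.0, 0.2, 21),
    "M": np.linspace(0.0, 4.0, 21),
    "phi": np.linspace(0.0, math.pi / 2, 21),
    "r0": np.linspace(0.01, 0.4, 21),
}
# Restricted grids for impedance responses (pole avoidance, see module docstring).
IMPEDANCE_GRIDS: dict[str, np.ndarray] = {
    **DEFAULT_GRIDS,
    "M": np.linspace(0.0, 3.0, 21),
    "r0": np.linspace(0.15, 0.4, 21),
}

FAMILY_DELTAS = (0.05, 0.10, 0.15)

#: radial probe position for the u_at_r column (the captions print r = 0.2)
PROBE_RADIUS = 0.2


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: a swept parameter, an optional curve family, fixed rest.

    ``station="auto"`` evaluates point quantities (tau_bar_w, u) at the
    midpoint of the lesion whose height is being swept (delta2 -> the
    dilatation), falling back to the first lesion's midpoint.
    """

    parameter: str
    grid: tuple[float, ...] = ()
    family_parameter: str | None = None
    family_values: tuple[float, ...] = ()
    station: float | str = "auto"

    def __post_init__(self) -> None:
        if self.parameter not in SWEEP_PARAMETERS:
            raise ValidationError(
                f"swept parameter must be one of {SWEEP_PARAMETERS}, got {self.parameter!r}"
            )
        if self.family_parameter is not None:
            if self.family_parameter not in SWEEP_PARAMETERS:
                raise ValidationError(f"unknown family parameter {self.family_parameter!r}")
            if self.family_parameter == self.parameter:
                raise ValidationError("swept and family parameters must be distinct")
            if len(self.family_values) == 0:
                raise ValidationError("family_values must be non-empty when family is set")
        grid = tuple(float(v) for v in self.grid)
        if len(grid) == 0:
            raise ValidationError("sweep grid must be non-empty")
        if len(grid) > 1 and any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValidationError("sweep grid must be sorted strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "family_values", tuple(float(v) for v in self.family_values))


def _apply_parameter(config: ModelConfig, name: str, value: float) -> ModelConfig:
    if name in ("delta1", "delta2"):
        idx = 0 if name == "delta1" else 1
        segs = list(config.geometry.segments)
        if len(segs) <= idx:
            raise ValidationError(
                f"config geometry lacks segment {idx + 1} needed to sweep {name}"
            )
        old = segs[idx]
        kind = "stenosis" if name == "delta1" else "dilatation"
        segs[idx] = AbnormalSegment.from_kind(kind, value, old.length, old.gap)
        geometry = VesselGeometry(
            segments=tuple(segs),
            reference_radius=config.geometry.reference_radius,
            domain_length=config.geometry.domain_length,
        )
        return config.with_(geometry=geometry)
    if name == "M":
        return config.with_(forces=ForceField(value, config.forces.gravity, config.forces.inclination))
    if name == "phi":
        return config.with_(forces=ForceField(config.forces.magnetization, config.forces.gravity, value))
    if name == "r0":
        return config.with_(plug_radius=value)
    raise ValidationError(f"unknown parameter {name!r}")


def _resolve_station(spec: SweepSpec, config: ModelConfig) -> float:
    if spec.station != "auto":
        return config.geometry.throat() if spec.station == "throat" else float(spec.station)
    idx = 1 if spec.parameter == "delta2" and len(config.geometry.segments) > 1 else 0
    return config.geometry.throat(idx)


def run_sweep(spec: SweepSpec, config: ModelConfig | None = None) -> pd.DataFrame:
    """Evaluate all responses over the sweep; long format, one row per point.

    Columns: parameter, swept, family_parameter, family, lambda_bar,
    tau_bar_w, u_center, u_at_r.  Deterministic: identical inputs give
    identical tables.  Any invalid station aborts the whole sweep.
    """
    base = config if config is not None else caption_defaults()
    family_values: Sequence[float | None] = (
        spec.family_values if spec.family_parameter else (None,)
    )
    rows = []
    for fam in family_values:
        cfg_fam = (
            _apply_parameter(base, spec.family_parameter, fam) if fam is not None else base
        )
        for val in spec.grid:
            cfg = _apply_parameter(cfg_fam, spec.parameter, val)
            z_star = _resolve_station(spec, cfg)
            try:
                lam_bar = axial_assembly.normalized_impedance(
                    cfg.flux, cfg.geometry, cfg.plug_radius, cfg.forces, cfg.mode,
                    cfg.quadrature_points,
                )
                tau_bar = axial_assembly.normalized_wss(
                    cfg.flux, cfg.geometry, cfg.plug_radius, cfg.forces, cfg.mode, z_star
                )
                H = wall_radius(z_star, cfg.geometry)
                D = drive(cfg.flux, H, cfg.plug_radius, cfg.forces, cfg.mode)
                u_center = axial_velocity(0.0, H, cfg.plug_radius, D)
                u_probe = axial_velocity(min(PROBE_RADIUS, H), H, cfg.plug_radius, D)
            except StenoflowError as exc:
                raise type(exc)(
                    f"sweep {spec.parameter}={val}"
                    + (f", {spec.family_parameter}={fam}" if fam is not None else "")
                    + f": {exc}"
                ) from exc
            rows.append(
                {
                    "parameter": spec.parameter,
                    "swept": val,
                    "family_parameter": spec.family_parameter or "",
                    "family": np.nan if fam is None else fam,
                    "lambda_bar": lam_bar,
                    "tau_bar_w": tau_bar,
                    "u_center": u_center,
                    "u_at_r": u_probe,
                }
            )
    return pd.DataFrame(rows)


def radial_profile_table(
    config: ModelConfig | None = None,
    station: float | str = "throat",
    points: int = 51,
) -> pd.DataFrame:
    """Velocity profile u(r) at one station, as a sweep-style table over r."""
    cfg = config if config is not None else caption_defaults()
    z_star = cfg.geometry.throat() if station == "throat" else float(station)
    H = wall_radius(z_star, cfg.geometry)
    D = drive(cfg.flux, H, cfg.plug_radius, cfg.forces, cfg.mode)
    r = np.linspace(0.0, H, points)
    u = np.asarray(axial_velocity(r, H, cfg.plug_radius, D), dtype=float)
    return pd.DataFrame(
        {
            "parameter": "r",
            "swept": r,
            "family_parameter": "",
            "family": np.nan,
            "u": u,
        }
    )


@dataclass(frozen=True)
class TrendExpectation:
    """An expected monotone direction for one response along one parameter.

    ``strict=False`` allows flat stretches (the plug core makes the radial
    velocity profile constant near the axis); ``wall_zero=True`` adds the
    no-slip check that the last grid value of the response is zero.
    """

    response: str
    parameter: str
    direction: str  # "increasing" | "decreasing"
    source: str = ""
    strict: bool = True
    wall_zero: bool = False
    atol: float = 0.0  # rounding allowance on each finite difference

    def __post_init__(self) -> None:
        if self.direction not in ("increasing", "decreasing"):
            raise ValidationError("direction must be 'increasing' or 'decreasing'")


@dataclass(frozen=True)
class TrendResult:
    expectation: TrendExpectation
    status: str  # PASS | FAIL | NOT-EVALUABLE
    worst_violation: float
    location: str = ""


_RESPONSE_FALLBACK = {"u": "u_center", "velocity": "u_center"}


def _response_column(table: pd.DataFrame, response: str) -> str:
    if response in table.columns:
        return response
    alt = _RESPONSE_FALLBACK.get(response)
    if alt and alt in table.columns:
        return alt
    raise ValidationError(f"table has no column for response {response!r}")


def monotonicity_report(
    table: pd.DataFrame, expectations: Sequence[TrendExpectation]
) -> list[TrendResult]:
    """Sign-test successive finite differences of each response per family."""
    results = []
    for exp in expectations:
        sub = table[table["parameter"] == exp.parameter]
        if sub.empty:
            results.append(TrendResult(exp, "NOT-EVALUABLE", 0.0, "no rows for parameter"))
            continue
        col = _response_column(sub, exp.response)
        sign = 1.0 if exp.direction == "increasing" else -1.0
        worst = 0.0
        loc = ""
        evaluable = False
        ok = True
        for fam, grp in sub.groupby("family", dropna=False, sort=False):
            grp = grp.sort_values("swept")
            if len(grp) < 2:
                continue
            evaluable = True
            diffs = sign * np.diff(grp[col].to_numpy())
            bad = (diffs <= -exp.atol) if exp.strict else (diffs < -exp.atol)
            if np.any(bad):
                ok = False
                i = int(np.argmin(diffs))
                if -diffs[i] > worst:
                    worst = float(-diffs[i])
                    loc = (
                        f"{exp.parameter}={grp['swept'].iloc[i]:.6g}"
                        + ("" if pd.isna(fam) else f", family={fam:.6g}")
                    )
        if exp.wall_zero and evaluable:
            tail = float(sub.sort_values("swept")[col].iloc[-1])
            if abs(tail) > 1e-12:
                ok = False
                worst = max(worst, abs(tail))
                loc = loc or "wall value nonzero"
        if not evaluable:
            results.append(TrendResult(exp, "NOT-EVALUABLE", 0.0, "grid too short"))
        else:
            results.append(TrendResult(exp, "PASS" if ok else "FAIL", worst, loc))
    return results


def default_expectations() -> tuple[TrendExpectation, ...]:
    """The shipped trend fixture: the source's headline directions.

    Impedance and wall shear rise with stenosis height and fall with
    dilatation height (the directions stated by the source's abstract and
    figure narrative; its concluding summary states the opposite for
    stenosis height, and the figure-level direction is the one encoded).
    Velocity falls with stenosis height, rises with dilatation height,
    rises with M and with phi, and decreases radially to zero at the wall.
    """
    return (
        TrendExpectation("lambda_bar", "delta1", "increasing", "figs 2, 4, 6, 8"),
        TrendExpectation("lambda_bar", "delta2", "decreasing", "figs 3, 5, 7, 9"),
        TrendExpectation("tau_bar_w", "delta1", "increasing", "figs 10, 12, 14, 16"),
        TrendExpectation("tau_bar_w", "delta2", "decreasing", "figs 11, 13, 15, 17"),
        TrendExpectation("u", "delta1", "decreasing", "fig 18"),
        TrendExpectation("u", "delta2", "increasing", "fig 19"),
        TrendExpectation("u", "M", "increasing", "figs 20, 21"),
        TrendExpectation("u", "phi", "increasing", "figs 22, 23"),
        TrendExpectation("u", "r", "decreasing", "radial no-slip profile",
                         strict=False, wall_zero=True, atol=1e-12),
    )


def normal_station(geometry: VesselGeometry) -> float:
    """Midpoint of the widest lesion-free axial interval (H = R0 there).

    The radial no-slip profile is checked at such a station: under the
    printed sign convention the caption-default drive is forward there,
    whereas at the stenosis throat it is retrograde (an artifact of that
    convention), which would invert the radial monotonicity.
    """
    edges = [0.0]
    for b in geometry.bounds:
        edges.extend((b.alpha, b.beta))
    edges.append(geometry.length)
    gaps = [(a, b) for a, b in zip(edges[::2], edges[1::2]) if b > a]
    if not gaps:
        return geometry.length / 2.0
    a, b = max(gaps, key=lambda ab: ab[1] - ab[0])
    return 0.5 * (a + b)


def run_trend_suite(config: ModelConfig | None = None) -> dict[str, pd.DataFrame]:
    """Sweeps backing the default expectations, keyed by swept parameter."""
    base = config if config is not None else caption_defaults()
    tables = {}
    for name, fam in (("delta1", "delta2"), ("delta2", "delta1"), ("M", "delta1"), ("phi", "delta1")):
        tables[name] = run_sweep(
            SweepSpec(name, tuple(DEFAULT_GRIDS[name]), fam, FAMILY_DELTAS), base
        )
    tables["r"] = radial_profile_table(base, station=normal_station(base.geometry))
    return tables


def evaluate_trends(config: ModelConfig | None = None) -> list[TrendResult]:
    """Run the default sweeps and check every shipped expectation."""
    tables = run_trend_suite(config)
    combined = pd.concat(tables.values(), ignore_index=True)
    return monotonicity_report(combined, default_expectations())


# ---------------------------------------------------------------------------
# Figure suite: one CSV (+ optional plot) per reproduced source figure.
# Keys are the figure numbers used in the source; values give the swept
# parameter, family parameter, and response column to plot.
# ---------------------------------------------------------------------------

FIGURE_SPECS: dict[str, dict] = {
    "fig02": {"response": "lambda_bar", "parameter": "r0", "family": "delta1"},
    "fig03": {"response": "lambda_bar", "parameter": "r0", "family": "delta2"},
    "fig04": {"response": "lambda_bar", "parameter": "M", "family": "delta1"},
    "fig05": {"response": "lambda_bar", "parameter": "M", "family": "delta2"},
    "fig06": {"response": "lambda_bar", "parameter": "phi", "family": "delta1"},
    "fig07": {"response": "lambda_bar", "parameter": "phi", "family": "delta2"},
    "fig08": {"response": "lambda_bar", "parameter": "delta1", "family": "delta2"},
    "fig09": {"response": "lambda_bar", "parameter": "delta2", "family": "delta1"},
    "fig10": {"response": "tau_bar_w", "parameter": "r0", "family": "delta1"},
    "fig11": {"response": "tau_bar_w", "parameter": "r0", "family": "delta2"},
    "fig12": {"response": "tau_bar_w", "parameter": "M", "family": "delta1"},
    "fig13": {"response": "tau_bar_w", "parameter": "M", "family": "delta2"},
    "fig14": {"response": "tau_bar_w", "parameter": "phi", "family": "delta1",
              "caption_transposed": True},
    "fig15": {"response": "tau_bar_w", "parameter": "phi", "family": "delta2",
              "caption_transposed": True},
    "fig16": {"response": "tau_bar_w", "parameter": "delta1", "family": "delta2"},
    "fig17": {"response": "tau_bar_w", "parameter": "delta2", "family": "delta1"},
    "fig18": {"response": "u_center", "parameter": "delta1", "family": "delta2"},
    "fig19": {"response": "u_center", "parameter": "delta2", "family": "delta1"},
    "fig20": {"response": "u_center", "parameter": "M", "family": "delta1"},
    "fig21": {"response": "u_center", "parameter": "M", "family": "delta2"},
    "fig22": {"response": "u_center", "parameter": "phi", "family": "delta1"},
    "fig23": {"response": "u_center", "parameter": "phi", "family": "delta2"},
    "fig24": {"response": "u_center", "parameter": "r0", "family": "delta1"},
    "fig25": {"response": "u_center", "parameter": "r0", "family": "delta2"},
}

# Literal transposed caption values for figs 14-15 (M and r0 swapped
# relative to every sibling caption).  r0 = 2.0 exceeds the lumen, so the
# literal reading cannot run; the suite records this in the metadata.
_TRANSPOSED_LITERAL = {"M": 0.2, "r0": 2.0}


def figure_spec_to_sweep(fig_id: str) -> SweepSpec:
    info = FIGURE_SPECS[fig_id]
    grids = IMPEDANCE_GRIDS if info["response"] == "lambda_bar" else DEFAULT_GRIDS
    return SweepSpec(
        parameter=info["parameter"],
        grid=tuple(grids[info["parameter"]]),
        family_parameter=info["family"],
        family_values=FAMILY_DELTAS,
    )


def _csv_bytes(table: pd.DataFrame) -> bytes:
    return table.to_csv(index=False, float_format="%.17g", lineterminator="\n").encode()


def figure_suite(
    config: ModelConfig | None = None,
    out_dir: str | Path = "figures",
    make_plots: bool = True,
) -> list[str]:
    """Regenerate every swept figure as CSV (and PNG), plus metadata.json.

    Returns the list of figure ids written.  Output is deterministic:
    repeated runs produce byte-identical CSVs.
    """
    base = config if config is not None else caption_defaults()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    metadata: dict[str, dict] = {}
    for fig_id, info in FIGURE_SPECS.items():
        spec = figure_spec_to_sweep(fig_id)
        table = run_sweep(spec, base)
        (out / f"{fig_id}.csv").write_bytes(_csv_bytes(table))
        meta = {
            "response": info["response"],
            "swept_parameter": info["parameter"],
            "family_parameter": info["family"],
        }
        if info.get("caption_transposed"):
            literal_error = ""
            try:  # the literal caption values: attempted, expected to fail
                cfg = _apply_parameter(
                    _apply_parameter(base, "M", _TRANSPOSED_LITERAL["M"]),
                    "r0", _TRANSPOSED_LITERAL["r0"],
                )
            except StenoflowError as exc:
                literal_error = str(exc)
            meta["caption_note"] = (
                "caption prints M=0.2, r=2.0 (transposed vs sibling captions); "
                "r0=2.0 exceeds the lumen so the literal values cannot run; "
                "the transposed values (M=2.0, r0=0.2) were used"
            )
            meta["literal_caption_error"] = literal_error or "plug_radius outside [0, 1)"
        metadata[fig_id] = meta
        if make_plots:
            _plot_figure(fig_id, info, table, out)
        written.append(fig_id)
    (out / "metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return written


_AXIS_LABELS = {
    "lambda_bar": r"$\bar{\lambda}$ (normalized impedance)",
    "tau_bar_w": r"$\bar{\tau}_w$ (normalized wall shear stress)",
    "u_center": r"$u$ (centerline velocity)",
    "delta1": r"$\delta_1$ (stenosis height)",
    "delta2": r"$\delta_2$ (dilatation height)",
    "M": r"$M$ (magnetization constant)",
    "phi": r"$\phi$ (inclination, rad)",
    "r0": r"$r_0$ (plug-core radius)",
}


def _plot_figure(fig_id: str, info: dict, table: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for fam, grp in table.groupby("family", dropna=False, sort=False):
        grp = grp.sort_values("swept")
        label = f"{info['family']}={fam:g}" if not pd.isna(fam) else None
        ax.plot(grp["swept"], grp[info["response"]], marker=".", label=label)
    ax.set_xlabel(_AXIS_LABELS.get(info["parameter"], info["parameter"]))
    ax.set_ylabel(_AXIS_LABELS.get(info["response"], info["response"]))
    ax.set_title(fig_id)
    if info["family"]:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / f"{fig_id}.png", dpi=110)
    plt.close(fig)
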