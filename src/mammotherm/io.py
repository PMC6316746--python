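"""Readers, writers and run configuration.

Chart files are plain CSV with a commented header carrying provenance, the
declared sweep grids and (for simulated charts) the tumor-free baselines.
Floats are serialized with ``repr`` so read(write(chart)) round-trips
bit-exactly.  Field and profile exports are plain delimited tables.

Run configurations are YAML with five blocks (scenario, solver,
tissue_healthy, tissue_tumor, boundary); unknown keys are rejected, and a
fully-populated default equals the packaged parameter set.  Temperatures may
be given as numbers (Kelvin) or strings with an explicit unit suffix,
e.g. ``"36.35 C"`` or ``"309.5 K"``; they are stored internally in Kelvin.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .bioheat import BoundarySpec, TemperatureField, TissueProps
from .charts import EstimationChart
from .defaults import (
    DEFAULT_BOUNDARY,
    DEFAULT_HEALTHY,
    DEFAULT_SPACING_MM,
    DEFAULT_TUMOR,
)
from .geometry import DomainSpec, Grid, OUTSIDE, REGION_NAMES, build_domain
from .surface import SurfaceProfile

__all__ = [
    "ConfigError",
    "RunConfig",
    "config_hash",
    "load_config",
    "default_config_dict",
    "read_chart",
    "write_chart",
    "write_field",
    "write_profile",
]

CHART_MAGIC = "# mammotherm chart v1"


class ConfigError(ValueError):
    """Invalid run configuration."""


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _atomic_write(path: Union[str, Path], text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ----------------------------------------------------------------- charts

def write_chart(chart: EstimationChart, path: Union[str, Path]) -> None:
    """Serialize a chart; full-precision dT plus a 2-decimal display column."""
    lines = [CHART_MAGIC]
    lines.append(f"# provenance: {chart.provenance}")
    lines.append(f"# position_mm: {chart.position[0]!r},{chart.position[1]!r}")
    lines.append("# r1_grid_mm: " + ",".join(repr(v) for v in chart.r1_grid))
    lines.append("# r2_grid_mm: " + ",".join(repr(v) for v in chart.r2_grid))
    if chart.baseline is not None:
        for r1 in chart.r1_grid:
            if r1 in chart.baseline:
                lines.append(f"# baseline_mm: R1={r1!r} dT={chart.baseline[r1]!r}")
    lines.append(
        "position_x_mm,position_y_mm,R1_mm,R2_mm,delta_T_C,delta_T_C_2dp,provenance"
    )
    px, py = chart.position
    for r1 in chart.r1_grid:
        for r2 in chart.r2_grid:
            dt = chart.entries[(r1, r2)]
            lines.append(
                f"{px!r},{py!r},{r1!r},{r2!r},{dt!r},{dt:.2f},{chart.provenance}"
            )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_chart(path: Union[str, Path]) -> EstimationChart:
    """Read a chart file written by :func:`write_chart` (bit-exact round trip)."""
    path = Path(path)
    provenance = "unknown"
    position: Optional[Tuple[float, float]] = None
    r1_grid: Tuple[float, ...] = ()
    r2_grid: Tuple[float, ...] = ()
    baseline: Dict[float, float] = {}
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            if line == CHART_MAGIC:
                header_seen = True
            elif line.startswith("# provenance:"):
                provenance = line.split(":", 1)[1].strip()
            elif line.startswith("# position_mm:"):
                a, b = line.split(":", 1)[1].split(",")
                position = (float(a), float(b))
            elif line.startswith("# r1_grid_mm:"):
                r1_grid = tuple(float(v) for v in line.split(":", 1)[1].split(","))
            elif line.startswith("# r2_grid_mm:"):
                r2_grid = tuple(float(v) for v in line.split(":", 1)[1].split(","))
            elif line.startswith("# baseline_mm:"):
                parts = dict(kv.split("=") for kv in line.split(":", 1)[1].split())
                baseline[float(parts["R1"])] = float(parts["dT"])
    if not header_seen:
        raise ValueError(f"{path} is not a mammotherm chart file")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    entries = {
        (float(row.R1_mm), float(row.R2_mm)): float(row.delta_T_C)
        for row in df.itertuples()
    }
    if position is None:
        position = (float(df.position_x_mm.iloc[0]), float(df.position_y_mm.iloc[0]))
    return EstimationChart(
        position=position,
        r1_grid=r1_grid or tuple(sorted({k[0] for k in entries})),
        r2_grid=r2_grid or tuple(sorted({k[1] for k in entries})),
        entries=entries,
        provenance=provenance,
        baseline=baseline or None,
    )


# --------------------------------------------------------- field / profile

def write_field(field: TemperatureField, path: Union[str, Path]) -> None:
    """Export the temperature field as a gridded delimited table."""
    grid = field.grid
    jj, ii = np.nonzero(grid.region != OUTSIDE)
    lines = ["x_mm,y_mm,region,T_K,T_C"]
    for j, i in zip(jj, ii):
        T = float(field.values[j, i])
        lines.append(
            f"{float(grid.x[i])!r},{float(grid.y[j])!r},"
            f"{REGION_NAMES[int(grid.region[j, i])]},{T!r},{T - 273.15!r}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def write_profile(profile: SurfaceProfile, grid: Grid, path: Union[str, Path]) -> None:
    """Export the skin-surface profile (theta, arc length, temperature)."""
    R = grid.spec.R1 if grid.spec is not None else float("nan")
    lines = ["theta_rad,arc_mm,T_K,T_C"]
    for th, T in zip(profile.theta, profile.T_surface):
        th, T = float(th), float(T)
        lines.append(f"{th!r},{th * R!r},{T!r},{T - 273.15!r}")
    _atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------- configuration

def _parse_temperature(value, key: str) -> float:
    """Accept Kelvin numbers or '<value> C'/'<value> K' strings."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        parts = value.strip().split()
        if len(parts) == 2 and parts[1] in ("C", "K", "degC", "degK"):
            num = float(parts[0])
            return num + 273.15 if parts[1] in ("C", "degC") else num
    raise ConfigError(
        f"temperature field '{key}' must be a Kelvin number or a string with a "
        f"unit suffix like '36.35 C' or '309.5 K', got {value!r}"
    )


_TEMPERATURE_KEYS = {"T_a", "T_f", "T_core"}

_TISSUE_KEYS = {"k", "rho", "c", "q_met", "omega_b", "rho_b", "c_b", "T_a"}
_BOUNDARY_KEYS = {"h_f", "epsilon", "sigma", "T_f", "T_core"}
_SCENARIO_KEYS = {"R1_mm", "tumor_x_mm", "tumor_y_mm", "R2_mm"}
_SOLVER_KEYS = {"spacing_mm", "tol", "max_iter", "mode", "dt_s", "t_end_s"}
_TOP_KEYS = {"scenario", "solver", "tissue_healthy", "tissue_tumor", "boundary", "log_level"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; defaults equal the packaged parameter set."""

    spec: DomainSpec
    spacing_mm: float
    tol: float
    max_iter: int
    mode: str          # 'steady' | 'transient'
    dt_s: float
    t_end_s: float
    healthy: TissueProps
    tumor: TissueProps
    boundary: BoundarySpec
    log_level: str
    raw: dict

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def default_config_dict() -> dict:
    """The fully-populated default configuration (tumor-free baseline scenario)."""
    return {
        "scenario": {"R1_mm": 60.0, "tumor_x_mm": 0.0, "tumor_y_mm": 10.0, "R2_mm": 0.0},
        "solver": {
            "spacing_mm": DEFAULT_SPACING_MM,
            "tol": 1e-8,
            "max_iter": 100,
            "mode": "steady",
            "dt_s": 100.0,
            "t_end_s": 10000.0,
        },
        "tissue_healthy": dataclasses.asdict(DEFAULT_HEALTHY),
        "tissue_tumor": dataclasses.asdict(DEFAULT_TUMOR),
        "boundary": dataclasses.asdict(DEFAULT_BOUNDARY),
        "log_level": "INFO",
    }


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def _deep_update(base: dict, extra: dict) -> None:
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val


def _merge(defaults: dict, user: dict) -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict):
            out[key] = _merge(dval, user.get(key, {}) or {})
        else:
            out[key] = user.get(key, dval)
    return out


def load_config(path: Union[str, Path, None] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing values take the packaged defaults; unknown keys anywhere raise
    :class:`ConfigError` naming them.
    """
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config root must be a mapping, got {type(user).__name__}")
    if overrides:
        _deep_update(user, overrides)

    _check_keys(user, _TOP_KEYS, "config")
    for block, allowed in (
        ("scenario", _SCENARIO_KEYS),
        ("solver", _SOLVER_KEYS),
        ("tissue_healthy", _TISSUE_KEYS | {"rho", "c"}),
        ("tissue_tumor", _TISSUE_KEYS | {"rho", "c"}),
        ("boundary", _BOUNDARY_KEYS),
    ):
        if block in user:
            if not isinstance(user[block], dict):
                raise ConfigError(f"config block '{block}' must be a mapping")
            _check_keys(user[block], allowed, f"config block '{block}'")

    cfg = _merge(default_config_dict(), user)

    for block in ("tissue_healthy", "tissue_tumor", "boundary"):
        for key in list(cfg[block]):
            if key in _TEMPERATURE_KEYS:
                cfg[block][key] = _parse_temperature(cfg[block][key], f"{block}.{key}")

    scen = cfg["scenario"]
    try:
        spec = build_domain(
            scen["R1_mm"], (scen["tumor_x_mm"], scen["tumor_y_mm"]), scen["R2_mm"]
        )
        healthy = TissueProps(**cfg["tissue_healthy"])
        tumor = TissueProps(**cfg["tissue_tumor"])
        boundary = BoundarySpec(**cfg["boundary"])
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    solver = cfg["solver"]
    if solver["mode"] not in ("steady", "transient"):
        raise ConfigError(f"solver.mode must be 'steady' or 'transient', got {solver['mode']!r}")
    for key in ("spacing_mm", "tol", "dt_s", "t_end_s"):
        if not (isinstance(solver[key], (int, float)) and solver[key] > 0):
            raise ConfigError(f"solver.{key} must be a positive number, got {solver[key]!r}")
    if not (isinstance(solver["max_iter"], int) and solver["max_iter"] > 0):
        raise ConfigError(f"solver.max_iter must be a positive integer, got {solver['max_iter']!r}")

    return RunConfig(
        spec=spec,
        spacing_mm=float(solver["spacing_mm"]),
        tol=float(solver["tol"]),
        max_iter=int(solver["max_iter"]),
        mode=solver["mode"],
        dt_s=float(solver["dt_s"]),
        t_end_s=float(solver["t_end_s"]),
        healthy=healthy,
        tumor=tumor,
        boundary=boundary,
        log_level=str(cfg["log_level"]),
        raw=cfg,
    )
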