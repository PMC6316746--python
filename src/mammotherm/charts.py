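"""Estimation charts and the inverse tumor-size estimator.

An estimation chart tabulates the steady surface temperature difference dT
(degC) as a function of breast radius R1 and tumor radius R2 for one tumor
position.  Charts come from two sources: the three published reference
charts packaged with this library (positions (10, 0), (10, 10) and (0, 10);
R1 = 40..80 mm in steps of 10, R2 = 1..10 mm), and simulated charts built
by sweeping the forward solver.

The inverse estimator answers the clinical question behind the reference charts:
given the breast radius and an observed surface dT, which tabulated tumor
size matches best?  Lookup is nearest-dT within the R1 column, no
interpolation; ties break toward the smallest R2 (the convention implied by
the published worked examples).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize

from .bioheat import BoundarySpec, TissueProps, solve_steady
from .defaults import DEFAULT_BOUNDARY, DEFAULT_HEALTHY, DEFAULT_TUMOR, DEFAULT_SPACING_MM
from .geometry import HEALTHY, TUMOR, DomainSpec, GeometryError, build_domain, build_mesh
from .surface import extract_surface_profile, surface_delta_t

__all__ = [
    "EstimationChart",
    "EstimateResult",
    "load_paper_charts",
    "build_chart",
    "estimate_tumor",
    "calibrate_tumor_props",
]

# Grouping tolerance for "equal" chart dT values when collecting tied
# candidates; published charts carry 2 decimals, simulated ones full floats.
_TIE_EPS = 1e-12

PAPER_POSITIONS: Tuple[Tuple[float, float], ...] = ((10.0, 0.0), (10.0, 10.0), (0.0, 10.0))


@dataclass
class EstimationChart:
    """Mapping (R1, R2) -> surface dT for one tumor position.

    ``baseline`` optionally stores the tumor-free dT per R1 for simulated
    charts (used by the presence flag); the published fixture charts tabulate
    pure contrast, so their baseline is zero.
    """

    position: Tuple[float, float]
    r1_grid: Tuple[float, ...]
    r2_grid: Tuple[float, ...]
    entries: Dict[Tuple[float, float], float]
    provenance: str = "simulated"
    baseline: Optional[Dict[float, float]] = None

    def __post_init__(self) -> None:
        self.position = (float(self.position[0]), float(self.position[1]))
        self.r1_grid = tuple(float(v) for v in self.r1_grid)
        self.r2_grid = tuple(float(v) for v in self.r2_grid)
        expected = {(r1, r2) for r1 in self.r1_grid for r2 in self.r2_grid}
        keys = {(float(a), float(b)) for a, b in self.entries}
        if keys != expected:
            raise ValueError(
                "chart entries must cover exactly the declared (R1, R2) grid; "
                f"{len(keys ^ expected)} keys differ"
            )
        for key, dt in self.entries.items():
            if not (dt >= 0 and math.isfinite(dt)):
                raise ValueError(f"chart dT must be finite and >= 0, got {dt} at {key}")

    def __getitem__(self, key: Tuple[float, float]) -> float:
        return self.entries[(float(key[0]), float(key[1]))]

    def column(self, R1: float) -> Tuple[Tuple[float, float], ...]:
        """(R2, dT) pairs for one breast radius, in R2 order."""
        R1 = float(R1)
        return tuple((r2, self.entries[(R1, r2)]) for r2 in self.r2_grid)


@dataclass(frozen=True)
class EstimateResult:
    """Outcome of an inverse chart lookup."""

    R2_est: float            # mm; smallest R2 among minimal-residual candidates
    residual: float          # |dT_chart - dT_obs|, degC
    tumor_present: bool
    candidates: Tuple[float, ...]  # all R2 tied at the minimal residual


def load_paper_charts() -> Dict[Tuple[float, float], EstimationChart]:
    """Load the three packaged reference charts, keyed by tumor position."""
    from importlib import resources

    from .io import read_chart

    charts: Dict[Tuple[float, float], EstimationChart] = {}
    pkg_data = resources.files("mammotherm").joinpath("data")
    for fname in ("chart_pos10_0.csv", "chart_pos10_10.csv", "chart_pos0_10.csv"):
        with resources.as_file(pkg_data.joinpath(fname)) as path:
            chart = read_chart(path)
        charts[chart.position] = chart
    return charts


def estimate_tumor(
    chart: EstimationChart,
    R1: float,
    delta_t_obs: float,
    baseline_margin: float = 0.05,
) -> EstimateResult:
    """Invert an observed surface dT to a tumor-size estimate.

    Nearest-dT lookup within the R1 column of ``chart``; ties break toward
    the smallest R2.  ``tumor_present`` is False when ``delta_t_obs`` does
    not exceed the stored tumor-free baseline by more than
    ``baseline_margin`` (degC); fixture charts have baseline 0.

    Raises ``KeyError`` when R1 is not a tabulated column (the procedure is
    a discrete chart lookup; no interpolation across R1).
    """
    R1 = float(R1)
    if delta_t_obs < 0:
        raise ValueError(f"observed dT must be >= 0, got {delta_t_obs}")
    if R1 not in chart.r1_grid:
        available = ", ".join(f"{v:g}" for v in chart.r1_grid)
        raise KeyError(f"R1={R1:g} mm is not tabulated; available R1 values: {available}")
    col = chart.column(R1)
    residuals = np.array([abs(dt - delta_t_obs) for _, dt in col])
    best = residuals.min()
    candidates = tuple(r2 for (r2, _), r in zip(col, residuals) if r <= best + _TIE_EPS)
    baseline = 0.0
    if chart.baseline is not None:
        baseline = chart.baseline.get(R1, 0.0)
    return EstimateResult(
        R2_est=min(candidates),
        residual=float(best),
        tumor_present=bool(delta_t_obs > baseline + baseline_margin),
        candidates=candidates,
    )


def _forward_delta_t(
    spec: DomainSpec,
    props_by_region: Dict[int, TissueProps],
    bc: BoundarySpec,
    spacing: float,
    tol: float,
) -> float:
    grid = build_mesh(spec, spacing)
    fieldT = solve_steady(grid, props_by_region, bc, tol=tol)
    return surface_delta_t(extract_surface_profile(fieldT))


def build_chart(
    position: Tuple[float, float],
    R1_grid: Sequence[float],
    R2_grid: Sequence[float],
    healthy: TissueProps = DEFAULT_HEALTHY,
    tumor: TissueProps = DEFAULT_TUMOR,
    bc: BoundarySpec = DEFAULT_BOUNDARY,
    spacing: float = DEFAULT_SPACING_MM,
    tol: float = 1e-8,
    include_baseline: bool = True,
) -> EstimationChart:
    """Sweep the forward solver over (R1, R2) and tabulate surface dT.

    Every combination is validated up front; an invalid geometry aborts the
    sweep naming the offending (R1, R2) pair.  When ``include_baseline`` is
    set, a tumor-free solve per R1 is stored as the chart baseline.
    """
    from .io import config_hash

    position = (float(position[0]), float(position[1]))
    specs: Dict[Tuple[float, float], DomainSpec] = {}
    for R1 in R1_grid:
        for R2 in R2_grid:
            try:
                specs[(float(R1), float(R2))] = build_domain(R1, position, R2)
            except GeometryError as exc:
                raise GeometryError(
                    f"invalid sweep geometry at position={position}, "
                    f"R1={R1} mm, R2={R2} mm: {exc}"
                ) from exc

    props = {HEALTHY: healthy, TUMOR: tumor}
    entries: Dict[Tuple[float, float], float] = {}
    baseline: Dict[float, float] = {}
    for R1 in R1_grid:
        if include_baseline:
            spec0 = build_domain(R1, position, 0.0)
            baseline[float(R1)] = _forward_delta_t(spec0, {HEALTHY: healthy}, bc, spacing, tol)
        for R2 in R2_grid:
            key = (float(R1), float(R2))
            entries[key] = _forward_delta_t(specs[key], props, bc, spacing, tol)

    cfg = {
        "position_mm": list(position),
        "R1_grid_mm": [float(v) for v in R1_grid],
        "R2_grid_mm": [float(v) for v in R2_grid],
        "spacing_mm": spacing,
        "tol": tol,
        "healthy": dataclasses.asdict(healthy),
        "tumor": dataclasses.asdict(tumor),
        "bc": dataclasses.asdict(bc),
    }
    return EstimationChart(
        position=position,
        r1_grid=tuple(float(v) for v in R1_grid),
        r2_grid=tuple(float(v) for v in R2_grid),
        entries=entries,
        provenance=f"simulated:{config_hash(cfg)}",
        baseline=baseline if include_baseline else None,
    )


def calibrate_tumor_props(
    target_chart: EstimationChart,
    free_params: Sequence[str] = ("q_met",),
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    subset: Optional[Iterable[Tuple[float, float]]] = None,
    healthy: TissueProps = DEFAULT_HEALTHY,
    tumor_start: TissueProps = DEFAULT_TUMOR,
    bc: BoundarySpec = DEFAULT_BOUNDARY,
    spacing: float = 1.0,
    tol: float = 1e-8,
    grid_points: int = 5,
) -> Tuple[TissueProps, dict]:
    """Fit tumor properties so simulated dT matches a target chart.

    Minimizes the sum of squared dT errors over ``subset`` (default: all
    chart entries) with a deterministic two-stage search: a uniform grid
    scan over the box ``bounds`` followed by a Nelder-Mead refinement
    clipped to the box.  ``free_params`` may contain ``"q_met"`` and/or
    ``"omega_b"``.  Returns the fitted TUMOR :class:`TissueProps` and a fit
    report with per-entry residuals.
    """
    allowed = {"q_met", "omega_b"}
    free = tuple(free_params)
    if not free or not set(free) <= allowed:
        raise ValueError(f"free_params must be a non-empty subset of {sorted(allowed)}")
    default_bounds = {"q_met": (0.0, 2e5), "omega_b": (0.0, 5e-3)}
    box = {p: tuple(map(float, (bounds or {}).get(p, default_bounds[p]))) for p in free}
    for p, (lo, hi) in box.items():
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError(f"bounds for {p} must be finite with lo < hi, got {(lo, hi)}")

    keys = [
        (float(a), float(b)) for a, b in (subset if subset is not None else target_chart.entries)
    ]
    for key in keys:
        if key not in target_chart.entries:
            raise ValueError(f"subset entry {key} not present in the target chart")
    targets = np.array([target_chart.entries[k] for k in keys])

    def make_props(theta: np.ndarray) -> TissueProps:
        updates = {p: float(np.clip(v, *box[p])) for p, v in zip(free, theta)}
        return dataclasses.replace(tumor_start, **updates)

    def objective(theta: np.ndarray) -> float:
        props = make_props(theta)
        sim = np.empty(len(keys))
        for i, (R1, R2) in enumerate(keys):
            spec = build_domain(R1, target_chart.position, R2)
            sim[i] = _forward_delta_t(spec, {HEALTHY: healthy, TUMOR: props}, bc, spacing, tol)
        val = float(np.sum((sim - targets) ** 2))
        if not math.isfinite(val):
            raise FloatingPointError(
                f"non-finite calibration objective at {dict(zip(free, theta))}"
            )
        return val

    # Work in box-scaled coordinates (each free parameter mapped to [0, 1])
    # so Nelder-Mead tolerances are meaningful across disparate magnitudes.
    lo = np.array([box[p][0] for p in free])
    hi = np.array([box[p][1] for p in free])

    def unscale(u: np.ndarray) -> np.ndarray:
        return lo + np.clip(np.asarray(u, dtype=float), 0.0, 1.0) * (hi - lo)

    # Stage 1: deterministic grid scan.
    axes = [np.linspace(0.0, 1.0, grid_points) for _ in free]
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=-1)
    scan = [(objective(unscale(pt)), tuple(pt)) for pt in pts]
    best_val, best_u = min(scan, key=lambda t: t[0])

    # Stage 2: local refinement, clipped to the box inside the objective.
    result = scipy.optimize.minimize(
        lambda u: objective(unscale(u)),
        np.asarray(best_u),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 200},
    )
    theta = unscale(result.x)
    if objective(theta) > best_val:
        theta = unscale(np.asarray(best_u))

    fitted = make_props(theta)
    sim = {}
    for R1, R2 in keys:
        spec = build_domain(R1, target_chart.position, R2)
        sim[(R1, R2)] = _forward_delta_t(
            spec, {HEALTHY: healthy, TUMOR: fitted}, bc, spacing, tol
        )
    report = {
        "free_params": dict(zip(free, (float(v) for v in theta))),
        "bounds": box,
        "objective": float(sum((sim[k] - target_chart.entries[k]) ** 2 for k in keys)),
        "residuals": {k: float(sim[k] - target_chart.entries[k]) for k in keys},
        "grid_scan_best": {
            "params": dict(zip(free, (float(v) for v in unscale(np.asarray(best_u))))),
            "objective": best_val,
        },
        "n_entries": len(keys),
        "spacing_mm": spacing,
    }
    return fitted, report
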