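"""Semicircular breast geometry and Cartesian rasterization.

The model domain is a semicircle of radius ``R1`` (the breast cross-section)
sitting on the chest wall, with the flat diameter on the x-axis and the skin
along the curved arc.  A circular tumor of radius ``R2`` may be embedded in
the tissue.  All lengths are millimetres; the origin is the centre of the
flat base and the domain occupies the upper half-plane (y >= 0).

Domains are rasterized onto a uniform, cell-centred Cartesian grid.  A cell
belongs to a region iff its centre lies inside that region's analytic shape
(no partial-volume weighting); geometric accuracy is obtained by mesh
refinement, not by cut cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

# Region labels.
OUTSIDE = 0
HEALTHY = 1
TUMOR = 2

REGION_NAMES = {OUTSIDE: "OUTSIDE", HEALTHY: "HEALTHY", TUMOR: "TUMOR"}


class GeometryError(ValueError):
    """Raised when a domain or mesh request violates a geometric constraint."""


@dataclass(frozen=True)
class DomainSpec:
    """Validated description of the breast domain.

    Parameters
    ----------
    R1 : float
        Breast (semicircle) radius, mm.  Must be positive.
    tumor_center : (float, float)
        Tumor centre (x, y), mm.  ``y >= 0``; the tumor disc must lie
        strictly inside the semicircle.  A centre on the base (y = 0) is
        allowed and models a half-disc inclusion on the chest wall.
    R2 : float
        Tumor radius, mm.  ``R2 = 0`` encodes a tumor-free domain.
    """

    R1: float
    tumor_center: Tuple[float, float] = (0.0, 0.0)
    R2: float = 0.0

    def __post_init__(self) -> None:
        if not (self.R1 > 0):
            raise GeometryError(f"breast radius must satisfy R1 > 0, got R1={self.R1}")
        if self.R2 < 0:
            raise GeometryError(f"tumor radius must satisfy R2 >= 0, got R2={self.R2}")
        object.__setattr__(
            self, "tumor_center", (float(self.tumor_center[0]), float(self.tumor_center[1]))
        )
        if self.R2 > 0:
            cx, cy = self.tumor_center
            if cy < 0:
                raise GeometryError(
                    f"tumor centre must lie in the upper half-plane (y >= 0), got y={cy}"
                )
            if math.hypot(cx, cy) + self.R2 >= self.R1:
                raise GeometryError(
                    "tumor crosses the breast boundary: require |center| + R2 < R1, "
                    f"got |({cx}, {cy})| + {self.R2} >= {self.R1}"
                )
            if 0 < cy < self.R2:
                raise GeometryError(
                    "tumor disc crosses the flat base: require center_y >= R2 "
                    f"or center_y = 0 (half-disc on the base), got center_y={cy}, R2={self.R2}"
                )

    @property
    def has_tumor(self) -> bool:
        return self.R2 > 0


def build_domain(
    R1: float, tumor_center: Tuple[float, float] = (0.0, 0.0), R2: float = 0.0
) -> DomainSpec:
    """Validate and return a :class:`DomainSpec` (lengths in mm)."""
    return DomainSpec(R1=float(R1), tumor_center=tuple(tumor_center), R2=float(R2))


def mirror_domain(spec: DomainSpec) -> DomainSpec:
    """Reflect the tumor position across the y-axis (bilateral mirror image)."""
    cx, cy = spec.tumor_center
    # -0.0 == 0.0, but normalize to keep mirror(mirror(s)) == s bitwise.
    mx = -cx if cx != 0 else 0.0
    return DomainSpec(R1=spec.R1, tumor_center=(mx, cy), R2=spec.R2)


@dataclass
class Grid:
    """Rasterized domain with region labels and boundary bookkeeping.

    Attributes
    ----------
    spacing : float
        Cell size, mm (uniform, square cells).
    nx, ny : int
        Cell counts along x and y.
    x, y : ndarray
        Cell-centre coordinates (mm), shapes (nx,), (ny,).
    region : ndarray of int8, shape (ny, nx)
        Per-cell label, one of OUTSIDE / HEALTHY / TUMOR.
    surface_ji : ndarray of int, shape (m, 2)
        (j, i) indices of curved-surface cells, ordered by increasing theta.
    surface_theta : ndarray, shape (m,)
        Polar angle of each surface-cell centre, radians.
    surface_nfaces : ndarray of int, shape (m,)
        Number of exposed staircase faces per surface cell.
    surface_gap : ndarray, shape (m,)
        Radial distance (mm) from the surface-cell centre to the analytic
        boundary arc (used as the conduction path length to the skin).
    base_i : ndarray of int
        Column indices of flat-base cells (row j = 0).
    kind : str
        'semicircle' (production), 'disc' or 'strip' (test geometries).
    face_scale : float
        Ratio of the analytic boundary length to the staircase length;
        exposed face areas are multiplied by it to remove the systematic
        staircase arc-length bias.
    spec : DomainSpec, optional
        Originating domain, when kind == 'semicircle'.
    """

    spacing: float
    nx: int
    ny: int
    x: np.ndarray
    y: np.ndarray
    region: np.ndarray
    surface_ji: np.ndarray
    surface_theta: np.ndarray
    surface_nfaces: np.ndarray
    surface_gap: np.ndarray
    base_i: np.ndarray
    kind: str = "semicircle"
    face_scale: float = 1.0
    spec: Optional[DomainSpec] = None

    @property
    def interior_mask(self) -> np.ndarray:
        return self.region != OUTSIDE

    @property
    def n_interior(self) -> int:
        return int(np.count_nonzero(self.region != OUTSIDE))

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-centre coordinates, shapes (ny, nx)."""
        return np.meshgrid(self.x, self.y)


def _exposed_faces(region: np.ndarray) -> np.ndarray:
    """Count, per cell, the 4-neighbour faces that open onto OUTSIDE cells.

    Array edges are not counted: meshes are built with at least one ring of
    OUTSIDE padding except along the flat base (row 0), which is the
    Dirichlet boundary, never a free surface.
    """
    inside = region != OUTSIDE
    out = ~inside
    count = np.zeros(region.shape, dtype=np.int64)
    count[:-1, :] += out[1:, :]   # north neighbour
    count[1:, :] += out[:-1, :]   # south neighbour
    count[:, :-1] += out[:, 1:]   # east neighbour
    count[:, 1:] += out[:, :-1]   # west neighbour
    count[out] = 0
    return count


def build_mesh(spec: DomainSpec, spacing: float) -> Grid:
    """Rasterize a breast domain onto a uniform cell-centred grid.

    The grid is symmetric about x = 0 (an even number of columns with
    centres at +/-(k + 1/2) h), so bilateral mirror images rasterize to
    exact x-flips of each other.

    Raises
    ------
    GeometryError
        If ``spacing <= 0`` or the tumor would span fewer than two cells
        across (``spacing > R2 / 2``).
    """
    if spacing <= 0:
        raise GeometryError(f"spacing must be positive, got {spacing}")
    if spec.R2 > 0 and spacing > spec.R2 / 2:
        raise GeometryError(
            f"spacing {spacing} mm is too coarse for a tumor of radius {spec.R2} mm; "
            f"use a finer mesh (spacing <= R2/2 = {spec.R2 / 2} mm) so the tumor "
            f"spans >= 2 cells across"
        )
    h = float(spacing)
    half = math.ceil(spec.R1 / h) + 1  # one ring of OUTSIDE padding at the sides/top
    nx = 2 * half
    ny = half
    x = (np.arange(nx) - nx / 2 + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(x, y)

    inside = X * X + Y * Y < spec.R1 * spec.R1
    region = np.where(inside, HEALTHY, OUTSIDE).astype(np.int8)
    if spec.R2 > 0:
        cx, cy = spec.tumor_center
        dx = X - cx
        dy = Y - cy
        tumor = dx * dx + dy * dy <= spec.R2 * spec.R2
        region[inside & tumor] = TUMOR

    nfaces = _exposed_faces(region)
    jj, ii = np.nonzero(nfaces > 0)
    theta = np.arctan2(y[jj], x[ii])
    order = np.argsort(theta, kind="stable")
    jj, ii, theta = jj[order], ii[order], theta[order]
    r_c = np.hypot(x[ii], y[jj])
    gap = spec.R1 - r_c

    staircase = float(nfaces.sum()) * h
    face_scale = math.pi * spec.R1 / staircase if staircase > 0 else 1.0

    base_i = np.nonzero(region[0, :] != OUTSIDE)[0]

    return Grid(
        spacing=h,
        nx=nx,
        ny=ny,
        x=x,
        y=y,
        region=region,
        surface_ji=np.column_stack([jj, ii]),
        surface_theta=theta,
        surface_nfaces=nfaces[jj, ii],
        surface_gap=gap,
        base_i=base_i,
        kind="semicircle",
        face_scale=face_scale,
        spec=spec,
    )


def build_disc_mesh(R: float, spacing: float) -> Grid:
    """Full-disc test grid (two mirrored semicircles), all-HEALTHY.

    Used by the closed-form disc-conduction oracle; the entire rim is a free
    surface (no flat base), theta in (-pi, pi].
    """
    if spacing <= 0 or R <= 0:
        raise GeometryError("disc mesh requires R > 0 and spacing > 0")
    h = float(spacing)
    half = math.ceil(R / h) + 1
    n = 2 * half
    x = (np.arange(n) - n / 2 + 0.5) * h
    y = x.copy()
    X, Y = np.meshgrid(x, y)
    region = np.where(X * X + Y * Y < R * R, HEALTHY, OUTSIDE).astype(np.int8)

    nfaces = _exposed_faces(region)
    jj, ii = np.nonzero(nfaces > 0)
    theta = np.arctan2(y[jj], x[ii])
    order = np.argsort(theta, kind="stable")
    jj, ii, theta = jj[order], ii[order], theta[order]
    gap = R - np.hypot(x[ii], y[jj])
    staircase = float(nfaces.sum()) * h
    face_scale = 2.0 * math.pi * R / staircase

    return Grid(
        spacing=h,
        nx=n,
        ny=n,
        x=x,
        y=y,
        region=region,
        surface_ji=np.column_stack([jj, ii]),
        surface_theta=theta,
        surface_nfaces=nfaces[jj, ii],
        surface_gap=gap,
        base_i=np.array([], dtype=np.int64),
        kind="disc",
        face_scale=face_scale,
        spec=None,
    )


def build_strip_mesh(length: float, width: float, spacing: float) -> Grid:
    """Tall thin rectangular strip exposing the solver's 1D limit.

    Dirichlet base at y = 0, free surface at y = length, insulated sides.
    ``surface_theta`` is a pseudo-angle (column position mapped to [0, pi])
    kept only so surface bookkeeping stays uniform across grid kinds.
    """
    if spacing <= 0 or length <= 0 or width <= 0:
        raise GeometryError("strip mesh requires positive length, width, spacing")
    h = float(spacing)
    ny = max(2, round(length / h))
    nx = max(1, round(width / h))
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    region = np.full((ny, nx), HEALTHY, dtype=np.int8)

    ii = np.arange(nx)
    jj = np.full(nx, ny - 1)
    theta = (ii + 0.5) / nx * math.pi
    gap = np.full(nx, h / 2.0)  # distance from the top-row centres to y = length

    return Grid(
        spacing=h,
        nx=nx,
        ny=ny,
        x=x,
        y=y,
        region=region,
        surface_ji=np.column_stack([jj, ii]),
        surface_theta=theta,
        surface_nfaces=np.ones(nx, dtype=np.int64),
        surface_gap=gap,
        base_i=np.arange(nx),
        kind="strip",
        face_scale=1.0,
        spec=None,
    )
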