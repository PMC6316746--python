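"""Skin-surface temperature profile and the diagnostic statistic dT.

The diagnostic used for tumor estimation is the surface temperature
difference: max minus min of the temperature along the curved (skin) arc,
reported in degrees Celsius.  The flat base is a boundary condition, not an
observable skin surface, so it is excluded from the profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bioheat import TemperatureField

__all__ = ["SurfaceProfile", "extract_surface_profile", "surface_delta_t", "max_temperature"]


@dataclass
class SurfaceProfile:
    """Temperatures along the curved skin arc, ordered by polar angle."""

    theta: np.ndarray      # radians, increasing
    T_surface: np.ndarray  # K, one value per surface cell

    def __len__(self) -> int:
        return len(self.theta)


def extract_surface_profile(field: TemperatureField) -> SurfaceProfile:
    """Read the field at the curved-surface cells, ordered by theta."""
    grid = field.grid
    if grid.surface_ji.shape[0] < 3:
        raise ValueError(
            f"grid has only {grid.surface_ji.shape[0]} surface cells; "
            "need >= 3 for a surface profile (refine the mesh)"
        )
    jj = grid.surface_ji[:, 0]
    ii = grid.surface_ji[:, 1]
    T = field.values[jj, ii]
    if not np.all(np.isfinite(T)):
        raise ValueError("non-finite temperatures on the surface")
    return SurfaceProfile(theta=grid.surface_theta.copy(), T_surface=T)


def surface_delta_t(profile: SurfaceProfile) -> float:
    """Surface temperature difference max(T) - min(T), degrees C.

    A Kelvin difference equals a Celsius difference, so no offset applies.
    """
    if len(profile) == 0:
        raise ValueError("empty surface profile")
    return float(profile.T_surface.max() - profile.T_surface.min())


def max_temperature(field: TemperatureField) -> tuple[float, tuple[float, float]]:
    """Maximum temperature over all tissue cells, in degrees C, with its
    cell-centre location (mm).  Ties break toward the lowest cell index
    (row-major flatten order)."""
    grid = field.grid
    vals = np.where(grid.interior_mask, field.values, -np.inf)
    flat = int(np.argmax(vals))  # first occurrence wins on ties
    j, i = np.unravel_index(flat, vals.shape)
    return float(vals[j, i] - 273.15), (float(grid.x[i]), float(grid.y[j]))
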