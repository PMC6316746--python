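"""Closed-form solutions and synthetic fields used as independent oracles.

Implemented without touching the production assembly code path: each oracle
is an elementary closed form on a simplified geometry (full disc with a
uniform source, 1D perfused slab).  The semicircular mixed-boundary problem
has no elementary solution; it is covered instead by convergence, symmetry
and energy-balance properties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .bioheat import TemperatureField
from .geometry import Grid

MM = 1e-3

__all__ = [
    "OracleCase",
    "disc_conduction_oracle",
    "perfused_slab_oracle",
    "make_synthetic_field",
]


@dataclass(frozen=True)
class OracleCase:
    """A named closed-form temperature field with a comparison tolerance."""

    name: str
    geometry: str
    params: dict
    evaluate: Callable[..., np.ndarray]  # coordinates in mm -> temperature, K
    tolerance: float

    def __post_init__(self) -> None:
        if not (self.tolerance > 0):
            raise ValueError("oracle tolerance must be positive")


def disc_conduction_oracle(R: float, k: float, q: float, T_b: float) -> OracleCase:
    """Steady conduction in a full disc with uniform source and Dirichlet rim.

    T(r) = T_b + q (R^2 - r^2) / (4 k),   0 <= r <= R,

    the radially symmetric steady limit of the polar heat equation.  The
    centre excess is q R^2 / (4 k).

    Parameters: R in mm, k in W/(m K), q in W/m^3, T_b in K.
    """
    if R <= 0 or k <= 0:
        raise ValueError("disc oracle requires R > 0 and k > 0")
    R_m = R * MM

    def evaluate(x_mm, y_mm):
        r_m = np.hypot(np.asarray(x_mm, dtype=float), np.asarray(y_mm, dtype=float)) * MM
        return T_b + q * (R_m**2 - r_m**2) / (4.0 * k)

    return OracleCase(
        name="disc_conduction",
        geometry=f"disc R={R} mm",
        params={"R_mm": R, "k": k, "q": q, "T_b": T_b},
        evaluate=evaluate,
        tolerance=0.01 * q * R_m**2 / (4.0 * k) if q != 0 else 1e-9,
    )


def perfused_slab_oracle(
    L: float, k: float, omega_b: float, rho_b: float, c_b: float, T0: float, T_a: float
) -> OracleCase:
    """1D steady perfused slab: Dirichlet T0 at x = 0, insulated at x = L.

    k T'' - omega_b rho_b c_b (T - T_a) = 0 has the closed form

        T(x) = T_a + (T0 - T_a) cosh(m (L - x)) / cosh(m L),
        m = sqrt(omega_b rho_b c_b / k).

    Parameters: L in mm; the rest SI.  For omega_b = 0 the solution is the
    constant T0 (no sink, no flux through the insulated end).
    """
    if L <= 0 or k <= 0 or omega_b < 0 or rho_b <= 0 or c_b <= 0:
        raise ValueError("perfused slab oracle requires positive parameters")
    L_m = L * MM
    m = math.sqrt(omega_b * rho_b * c_b / k)

    def evaluate(x_mm):
        x_m = np.asarray(x_mm, dtype=float) * MM
        if m == 0.0:
            return np.full_like(x_m, T0, dtype=float)
        return T_a + (T0 - T_a) * np.cosh(m * (L_m - x_m)) / np.cosh(m * L_m)

    return OracleCase(
        name="perfused_slab",
        geometry=f"strip L={L} mm",
        params={"L_mm": L, "k": k, "omega_b": omega_b, "rho_b": rho_b,
                "c_b": c_b, "T0": T0, "T_a": T_a, "m_per_m": m},
        evaluate=evaluate,
        tolerance=0.005 * abs(T0 - T_a) if T0 != T_a else 1e-9,
    )


def make_synthetic_field(grid: Grid, expression: Callable[[np.ndarray, np.ndarray], np.ndarray]) -> TemperatureField:
    """Populate a TemperatureField by direct evaluation of ``expression(x, y)``
    (mm coordinates, Kelvin result), bypassing the solver entirely.  Used to
    test the surface-analysis layer against analytic restrictions."""
    X, Y = grid.cell_centers()
    vals = np.asarray(expression(X, Y), dtype=float)
    if np.isscalar(vals) or vals.shape != X.shape:
        vals = np.broadcast_to(np.asarray(vals, dtype=float), X.shape).copy()
    else:
        vals = vals.copy()
    if not np.all(np.isfinite(vals[grid.interior_mask])):
        raise ValueError("synthetic expression is non-finite inside the domain")
    vals[~grid.interior_mask] = np.nan
    return TemperatureField(grid=grid, values=vals, meta={"mode": "synthetic"})
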