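"""Solid-angle geometry for the sphere-in-cell quadrature.

The cell is two concentric spheres (cell radius ``r_cell``, nucleus
radius ``r_nucleus``); a spherically symmetric dose source sits at
distance ``d`` from the cell center.  Because the source field depends
on the radius r only, volume integrals over a sensitive region reduce to
one-dimensional integrals of Omega(r) * r^2, where Omega(r) is the solid
angle of the part of the sphere of radius r (about the source) lying
inside the region.  Omega is piecewise analytic:

    Omega = 4*pi                                     r <= R - d
    Omega = 0                                        r >= d + R or r <= d - R
    Omega = 2*pi * (1 - (r^2 + d^2 - R^2)/(2 r d))   otherwise (spherical cap)

and Omega(r) * r^2 has a polynomial antiderivative on each piece, so
per-bin integrals are exact (no numerical quadrature).

Internal length unit is nm throughout; cell-scale defaults are given in
um at the constructor interface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "CellGeometry",
    "Region",
    "cap_solid_angle",
    "region_solid_angle",
    "omega_r2_bin_integral",
    "omega_r2_bin_integrals",
    "covered_volume",
    "region_volume",
]

_FOUR_PI = 4.0 * np.pi
_UM = 1000.0  # nm per um


class Region(str, Enum):
    """Sensitive volume: nucleus, whole cell, or cytoplasm (cell - nucleus)."""

    NUCLEUS = "nucleus"
    CELL = "cell"
    CYTOPLASM = "cytoplasm"


@dataclass(frozen=True)
class CellGeometry:
    """Concentric-sphere cell with a source offset, all lengths in nm."""

    r_cell: float = 15.0 * _UM
    r_nucleus: float = 7.0 * _UM
    d: float = 0.0  # distance from cell center to source center

    def __post_init__(self) -> None:
        if not (0 < self.r_nucleus < self.r_cell):
            raise ValueError("need 0 < r_nucleus < r_cell")
        if self.d < 0:
            raise ValueError("source offset d must be >= 0")

    @classmethod
    def from_um(
        cls, r_cell_um: float = 15.0, r_nucleus_um: float = 7.0, d_um: float = 0.0
    ) -> "CellGeometry":
        return cls(r_cell=r_cell_um * _UM, r_nucleus=r_nucleus_um * _UM, d=d_um * _UM)

    def at(self, d: float) -> "CellGeometry":
        """Same cell with the source moved to offset ``d`` (nm)."""
        return replace(self, d=d)


def cap_solid_angle(r, d: float, R: float):
    """Solid angle (sr) of the sphere-of-radius-r arc inside a target ball.

    The target ball has radius ``R`` with center at distance ``d`` from
    the source.  Symmetric under r <-> d; continuous at the regime
    boundaries (tangency resolved by the limit).  Accepts scalar or array
    ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or d < 0 or R <= 0:
        raise ValueError("need r >= 0, d >= 0, R > 0")
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    out = np.zeros_like(r)
    full = r <= R - d
    out[full] = _FOUR_PI
    partial = (~full) & (r > abs(d - R)) & (r < d + R)
    if np.any(partial):
        rp = r[partial]
        # d > 0 here: for d == 0 the partial band (|d-R|, d+R) is empty.
        cos_theta = (rp**2 + d**2 - R**2) / (2.0 * rp * d)
        out[partial] = 2.0 * np.pi * (1.0 - cos_theta)
    return float(out[0]) if scalar else out


def region_solid_angle(r, geom: CellGeometry, region: Region):
    """Omega(r) for a sensitive region of the cell (cytoplasm by difference)."""
    region = Region(region)
    if region is Region.NUCLEUS:
        return cap_solid_angle(r, geom.d, geom.r_nucleus)
    if region is Region.CELL:
        return cap_solid_angle(r, geom.d, geom.r_cell)
    cyt = np.asarray(
        cap_solid_angle(r, geom.d, geom.r_cell)
        - cap_solid_angle(r, geom.d, geom.r_nucleus)
    )
    cyt = np.clip(cyt, 0.0, None)
    return float(cyt) if cyt.ndim == 0 else cyt


def _cap_cumulative(r, d, R: float):
    """F(r) = integral_0^r Omega(s; d, R) s^2 ds, exact, broadcastable.

    On the partial-cap regime the integrand is
    2*pi*s^2 - pi*(s^3 + s*(d^2 - R^2))/d with antiderivative
    G(s) = (2*pi/3) s^3 - (pi/d) (s^4/4 + (d^2 - R^2) s^2 / 2).
    """
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    r, d = np.broadcast_arrays(r, d)
    p_lo = np.abs(d - R)
    p_hi = d + R
    # Fully covered inner part (only when the source is inside the target).
    full_edge = np.maximum(R - d, 0.0)
    out = (_FOUR_PI / 3.0) * np.minimum(r, full_edge) ** 3
    t = np.clip(r, p_lo, p_hi)
    d_safe = np.where(d > 0, d, 1.0)

    def g(s):
        return (2.0 * np.pi / 3.0) * s**3 - (np.pi / d_safe) * (
            s**4 / 4.0 + (d**2 - R**2) * s**2 / 2.0
        )

    partial = np.where((d > 0) & (t > p_lo), g(t) - g(p_lo), 0.0)
    return out + partial


def _region_cumulative(r, d, geom: CellGeometry, region: Region):
    region = Region(region)
    if region is Region.NUCLEUS:
        return _cap_cumulative(r, d, geom.r_nucleus)
    if region is Region.CELL:
        return _cap_cumulative(r, d, geom.r_cell)
    return _cap_cumulative(r, d, geom.r_cell) - _cap_cumulative(r, d, geom.r_nucleus)


def omega_r2_bin_integral(
    r_lo: float, r_hi: float, geom: CellGeometry, region: Region
) -> float:
    """Exact integral of Omega(r) r^2 over one radial bin [r_lo, r_hi)."""
    if not r_lo < r_hi:
        raise ValueError("need r_lo < r_hi")
    lo = _region_cumulative(r_lo, geom.d, geom, region)
    hi = _region_cumulative(r_hi, geom.d, geom, region)
    return float(hi - lo)


def omega_r2_bin_integrals(edges: np.ndarray, geom: CellGeometry, region: Region, d=None):
    """Per-bin integrals of Omega r^2 for all bins of a radial grid.

    ``d`` may be an array of source offsets (nm); the result then has
    shape ``(len(d), len(edges) - 1)``.  With ``d=None`` the geometry's
    own offset is used and the result is 1-D.
    """
    edges = np.asarray(edges, dtype=float)
    if d is None:
        cum = _region_cumulative(edges, geom.d, geom, region)
        return np.diff(cum)
    d = np.atleast_1d(np.asarray(d, dtype=float))
    cum = _region_cumulative(edges[None, :], d[:, None], geom, region)
    return np.diff(cum, axis=1)


def covered_volume(geom: CellGeometry, region: Region, r_max: float) -> float:
    """Volume of region intersected with the ball of radius r_max at the source."""
    if r_max < 0:
        raise ValueError("r_max must be >= 0")
    return float(_region_cumulative(r_max, geom.d, geom, region))


def region_volume(geom: CellGeometry, region: Region) -> float:
    """Total volume (nm^3) of a sensitive region."""
    region = Region(region)
    if region is Region.NUCLEUS:
        return (_FOUR_PI / 3.0) * geom.r_nucleus**3
    if region is Region.CELL:
        return (_FOUR_PI / 3.0) * geom.r_cell**3
    return (_FOUR_PI / 3.0) * (geom.r_cell**3 - geom.r_nucleus**3)
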