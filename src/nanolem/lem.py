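"""Local effect model (LEM) core mathematics.

The LEM maps a spatially varying local dose D_loc(r) = D + d(r) — a
macroscopic prescription D plus the nanoparticle dose field d(r) — into
an expected number of lethal lesions via the linear-quadratic response
averaged over a sensitive volume V:

    N = (1/V) * integral[ alpha*D_loc + beta*D_loc^2 ] dV
      = alpha*D + beta*D^2 + (alpha*I1 + beta*I2 + 2*beta*D*I1) / V

with I1 = integral d(r) dV and I2 = integral d(r)^2 dV over the
sensitive volume.  Under spherical symmetry about the source,
I1 = sum_bins D_bin * integral_bin Omega(r) r^2 dr, evaluated exactly
per bin (piecewise-constant dose, closed-form solid-angle integral).

The radiosensitizer enhancement factor SEF = I1*(alpha + 2*beta*D) /
(V*(alpha*D + beta*D^2)) is the I2-neglected relative excess of N over
the plain LQ baseline; I2's contribution is orders of magnitude below
I1's at therapeutic dose scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import CellGeometry, Region, omega_r2_bin_integrals, region_volume
from .rdd import RadialDoseDistribution

__all__ = [
    "CellLineParams",
    "LemResult",
    "s1_profile",
    "s2_profile",
    "compute_i1",
    "compute_i2",
    "lethal_lesions",
    "sef",
    "def_profile",
    "percent_diff",
]

_FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class CellLineParams:
    """Linear-quadratic coefficients and the macroscopic prescribed dose.

    Defaults (alpha = 0.2 / Gy, beta = 0.05 / Gy^2, D = 2 Gy) are generic
    configuration values in the range typical of mammalian lines, not a
    measurement of any particular cell line.
    """

    alpha: float = 0.2  # 1/Gy
    beta: float = 0.05  # 1/Gy^2
    dose_gy: float = 2.0  # macroscopic dose D

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")
        if self.dose_gy < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class LemResult:
    """LEM summary for one source position and sensitive region."""

    i1: float  # Gy nm^3
    i2: float  # Gy^2 nm^3
    v_sens: float  # nm^3
    n_total: float
    sef: float
    region: Region
    d: float  # source offset, nm
    flags: tuple[str, ...] = ()


def s1_profile(rdd: RadialDoseDistribution) -> np.ndarray:
    """Surface integral of dose at each bin midpoint: S1 = 4*pi*r^2*D(r)."""
    return _FOUR_PI * rdd.grid.mid**2 * rdd.dose


def s2_profile(rdd: RadialDoseDistribution) -> np.ndarray:
    """Surface integral of dose squared: S2 = 4*pi*r^2*D(r)^2."""
    return _FOUR_PI * rdd.grid.mid**2 * rdd.dose**2


def _check_source_clearance(rdd: RadialDoseDistribution, geom: CellGeometry, region: Region) -> bool:
    """True (with a warning) when the source sphere overlaps the region."""
    r_src = rdd.grid.source_radius
    region = Region(region)
    if region is Region.NUCLEUS:
        overlap = geom.d < geom.r_nucleus + r_src
    elif region is Region.CELL:
        overlap = geom.d < geom.r_cell + r_src
    else:
        overlap = (geom.d + r_src > geom.r_nucleus) and (geom.d - r_src < geom.r_cell)
    if overlap:
        warnings.warn(
            f"source sphere (r={r_src:g} nm) overlaps region {region.value} "
            f"at d={geom.d:g} nm; dose inside the source is not scored",
            stacklevel=3,
        )
    return overlap


def compute_i1(
    rdd: RadialDoseDistribution, geom: CellGeometry, region: Region
) -> float:
    """I1 = integral of the nanoparticle dose field over the region (Gy nm^3)."""
    _check_source_clearance(rdd, geom, region)
    w = omega_r2_bin_integrals(rdd.grid.edges, geom, region)
    return float(np.sum(rdd.dose * w))


def compute_i2(
    rdd: RadialDoseDistribution, geom: CellGeometry, region: Region
) -> float:
    """I2 = integral of the squared dose field over the region (Gy^2 nm^3)."""
    _check_source_clearance(rdd, geom, region)
    w = omega_r2_bin_integrals(rdd.grid.edges, geom, region)
    return float(np.sum(rdd.dose**2 * w))


def lethal_lesions(i1: float, i2: float, v_sens: float, cl: CellLineParams) -> float:
    """Expected lethal lesions N = aD + bD^2 + (a*I1 + b*I2 + 2bD*I1)/V.

    Reduces exactly to the LQ baseline for I1 = I2 = 0, and to
    a(D+d0) + b(D+d0)^2 for a uniform extra dose d0 over the region.
    """
    if v_sens <= 0:
        raise ValueError("v_sens must be positive")
    a, b, d = cl.alpha, cl.beta, cl.dose_gy
    return a * d + b * d**2 + (a * i1 + b * i2 + 2.0 * b * d * i1) / v_sens


def sef(i1: float, v_sens: float, cl: CellLineParams) -> float:
    """Radiosensitizer enhancement factor (I2-neglected excess over LQ)."""
    if cl.dose_gy <= 0:
        raise ValueError("SEF undefined at zero macroscopic dose")
    if v_sens <= 0:
        raise ValueError("v_sens must be positive")
    a, b, d = cl.alpha, cl.beta, cl.dose_gy
    return i1 * (a + 2.0 * b * d) / (v_sens * (a * d + b * d**2))


def def_profile(
    test: RadialDoseDistribution, ref: RadialDoseDistribution
) -> np.ndarray:
    """Per-bin dose enhancement factor DEF(r) = D_test(r) / D_ref(r).

    Reference bins with zero dose yield NaN (undefined marker), never an
    exception.  The grids must match.
    """
    if test.grid.n_bins != ref.grid.n_bins or not np.array_equal(
        test.grid.edges, ref.grid.edges
    ):
        raise ValueError("DEF requires identical radial grids")
    out = np.full(ref.dose.shape, np.nan)
    nz = ref.dose != 0
    out[nz] = test.dose[nz] / ref.dose[nz]
    return out


def percent_diff(x_mix, x_cluster):
    """Signed percentage difference (x_mix - x_cluster) * 100 / x_cluster.

    Negative values mean the cluster exceeds the mixture.  Zero cluster
    values yield NaN markers.  Accepts scalars or arrays.
    """
    x_mix = np.asarray(x_mix, dtype=float)
    x_cluster = np.asarray(x_cluster, dtype=float)
    scalar = x_mix.ndim == 0 and x_cluster.ndim == 0
    x_mix, x_cluster = np.atleast_1d(x_mix), np.atleast_1d(x_cluster)
    out = np.full(np.broadcast(x_mix, x_cluster).shape, np.nan)
    nz = np.broadcast_to(x_cluster != 0, out.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (x_mix - x_cluster) * 100.0 / x_cluster
    out[nz] = np.broadcast_to(vals, out.shape)[nz]
    return float(out[0]) if scalar else out


def lem_result(
    rdd: RadialDoseDistribution,
    geom: CellGeometry,
    region: Region,
    cl: CellLineParams,
    dose_scale: float = 1.0,
    flags: tuple[str, ...] = (),
) -> LemResult:
    """Convenience bundle: I1, I2, N_total and SEF for one placement."""
    scaled = rdd if dose_scale == 1.0 else rdd.scaled(dose_scale)
    i1 = compute_i1(scaled, geom, region)
    i2 = compute_i2(scaled, geom, region)
    v = region_volume(geom, region)
    return LemResult(
        i1=i1,
        i2=i2,
        v_sens=v,
        n_total=lethal_lesions(i1, i2, v, cl),
        sef=sef(i1, v, cl),
        region=Region(region),
        d=geom.d,
        flags=flags,
    )
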