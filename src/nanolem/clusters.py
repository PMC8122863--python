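"""Geometric composition of nanoparticle clusters.

A cluster is modelled as ``n_np`` equal hard spheres of radius ``r_np``
(gold) placed without overlap inside a bounding sphere of radius
``r_bound`` filled with water.  The homogeneous-mixture surrogate
("MixNP") is a single sphere of radius ``r_bound`` whose density carries
the same total gold mass; a two-shell variant concentrates the gold in an
inner core surrounded by a pure-water shell, emulating the depleted gold
concentration near a real cluster's surface.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

__all__ = [
    "GOLD_DENSITY",
    "WATER_DENSITY",
    "RSA_FEASIBILITY_LIMIT",
    "ClusterSpec",
    "ClusterRealization",
    "TwoShellMixSpec",
    "RadialGoldProfile",
    "InfeasibleSpecError",
    "PackingError",
    "EstimationError",
    "gold_volume_fraction",
    "mixture_density",
    "sample_cluster",
    "validate_realization",
    "radial_gold_fraction",
    "two_shell_equivalent",
    "write_cluster",
    "read_cluster",
]

#: Bulk density of gold, g/cm^3.
GOLD_DENSITY = 19.32
#: Density of liquid water, g/cm^3.
WATER_DENSITY = 1.0
#: Random sequential addition saturates near a packing fraction of 0.38
#: for equal hard spheres; requests above this fail fast.
RSA_FEASIBILITY_LIMIT = 0.38


class InfeasibleSpecError(ValueError):
    """The requested gold volume fraction exceeds 1 (spheres cannot fit)."""


class PackingError(RuntimeError):
    """Non-overlapping placement could not be achieved."""


class EstimationError(RuntimeError):
    """A Monte Carlo estimate is undefined (e.g. an empty shell)."""


@dataclass(frozen=True)
class ClusterSpec:
    """Specification of a nanoparticle cluster.

    Parameters
    ----------
    n_np
        Number of nanoparticles.
    r_np
        Nanoparticle radius, nm.
    r_bound
        Radius of the bounding (water) sphere, nm.
    rho_gold, rho_water
        Mass densities of the two components, g/cm^3.
    """

    n_np: int
    r_np: float
    r_bound: float
    rho_gold: float = GOLD_DENSITY
    rho_water: float = WATER_DENSITY

    def __post_init__(self) -> None:
        if self.n_np < 1:
            raise ValueError(f"n_np must be >= 1, got {self.n_np}")
        if not (0 < self.r_np <= self.r_bound):
            raise ValueError(
                f"need 0 < r_np <= r_bound, got r_np={self.r_np}, r_bound={self.r_bound}"
            )
        if self.rho_gold <= 0 or self.rho_water <= 0:
            raise ValueError("densities must be positive")


@dataclass(frozen=True)
class ClusterRealization:
    """A concrete non-overlapping placement of nanoparticle centers."""

    spec: ClusterSpec
    centers: np.ndarray  # shape (n_np, 3), nm
    seed: int

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.shape != (self.spec.n_np, 3):
            raise ValueError(
                f"centers must have shape ({self.spec.n_np}, 3), got {centers.shape}"
            )
        object.__setattr__(self, "centers", centers)


@dataclass(frozen=True)
class TwoShellMixSpec:
    """Two-concentric-sphere mixture: gold/water core, pure-water shell."""

    r_inner: float
    r_outer: float
    rho_inner: float
    rho_outer: float = WATER_DENSITY

    def __post_init__(self) -> None:
        if not (0 < self.r_inner < self.r_outer):
            raise ValueError("need 0 < r_inner < r_outer")


@dataclass(frozen=True)
class RadialGoldProfile:
    """Per-shell Monte Carlo estimate of the gold volume fraction."""

    shell_edges: np.ndarray  # nm, length n_shells + 1
    fraction: np.ndarray  # in [0, 1], length n_shells
    n_samples: np.ndarray  # points landing in each shell

    def volume_weighted_mean(self) -> float:
        """Shell-volume-weighted mean fraction over the bounding sphere."""
        vols = np.diff(self.shell_edges**3)
        return float(np.sum(self.fraction * vols) / np.sum(vols))


def gold_volume_fraction(spec: ClusterSpec) -> float:
    """Volume fraction of gold inside the bounding sphere.

    Equals ``n_np * (r_np / r_bound)**3``; raises
    :class:`InfeasibleSpecError` if this exceeds 1.
    """
    f = spec.n_np * (spec.r_np / spec.r_bound) ** 3
    if f > 1.0:
        raise InfeasibleSpecError(
            f"gold volume fraction {f:.3f} > 1: {spec.n_np} spheres of radius "
            f"{spec.r_np} nm cannot fit in a {spec.r_bound} nm sphere"
        )
    return f


def mixture_density(spec: ClusterSpec) -> float:
    """Effective density (g/cm^3) of the homogeneous gold-water mixture.

    The MixNP sphere carries the cluster's total gold mass plus
    interstitial water: rho = f*rho_gold + (1-f)*rho_water.
    """
    f = gold_volume_fraction(spec)
    return f * spec.rho_gold + (1.0 - f) * spec.rho_water


def _uniform_in_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def sample_cluster(
    spec: ClusterSpec,
    seed: int,
    max_attempts: int = 200_000,
    max_relax_iters: int = 20_000,
) -> ClusterRealization:
    """Place ``n_np`` non-overlapping nanoparticles uniformly in the bound.

    Random sequential addition (uniform proposals inside radius
    ``r_bound - r_np``) runs first; if it stalls before reaching ``n_np``
    — the target fraction 0.333 sits close to the RSA saturation limit —
    the remaining spheres are seeded at random and overlaps are resolved
    by repeated small pairwise displacements (relaxation), re-projecting
    escapees back inside the bound.  Identical seeds give identical
    centers.
    """
    f = gold_volume_fraction(spec)
    if f > RSA_FEASIBILITY_LIMIT:
        raise PackingError(
            f"gold volume fraction {f:.3f} exceeds the packing feasibility "
            f"bound {RSA_FEASIBILITY_LIMIT}; refusing to attempt (0 of "
            f"{spec.n_np} placed)"
        )
    rng = np.random.default_rng(seed)
    r_free = spec.r_bound - spec.r_np
    min_sep = 2.0 * spec.r_np

    buf = np.empty((spec.n_np, 3))
    n_placed = 0
    attempts = 0
    while n_placed < spec.n_np and attempts < max_attempts:
        attempts += 1
        cand = _uniform_in_ball(rng, 1, r_free)[0]
        if n_placed and np.min(
            np.linalg.norm(buf[:n_placed] - cand, axis=1)
        ) < min_sep:
            continue
        buf[n_placed] = cand
        n_placed += 1

    pos = buf[:n_placed].copy()
    n_missing = spec.n_np - n_placed
    if n_missing > 0:
        pos = np.vstack([pos, _uniform_in_ball(rng, n_missing, r_free)])
        pos = _relax_overlaps(pos, r_free, min_sep, rng, max_relax_iters)
        if pos is None:
            raise PackingError(
                f"packing failed: RSA placed {n_placed} of {spec.n_np} "
                f"and relaxation did not converge in {max_relax_iters} iterations"
            )

    real = ClusterRealization(spec=spec, centers=pos, seed=seed)
    validate_realization(real)
    return real


def _relax_overlaps(
    pos: np.ndarray,
    r_free: float,
    min_sep: float,
    rng: np.random.Generator,
    max_iters: int,
) -> np.ndarray | None:
    """Push overlapping pairs apart until hard-sphere constraints hold."""
    # Push toward a slightly padded separation; accept once no pair is
    # below min_sep beyond floating-point tolerance.
    target = min_sep * (1.0 + 1e-7)
    tol = min_sep * 1e-12
    for _ in range(max_iters):
        norms = np.linalg.norm(pos, axis=1)
        outside = norms > r_free
        if np.any(outside):
            pos[outside] *= (r_free / norms[outside])[:, None]
        tree = cKDTree(pos)
        pairs = tree.query_pairs(target, output_type="ndarray")
        if pairs.size == 0:
            return pos
        i, j = pairs[:, 0], pairs[:, 1]
        delta = pos[i] - pos[j]
        dist = np.linalg.norm(delta, axis=1)
        if np.all(dist >= min_sep - tol):
            return pos
        # Coincident points get a random push direction.
        bad = dist < 1e-12
        if np.any(bad):
            delta[bad] = rng.normal(size=(int(bad.sum()), 3))
            dist[bad] = np.linalg.norm(delta[bad], axis=1)
        unit = delta / dist[:, None]
        push = 0.5 * (target - dist) * 1.05
        disp = np.zeros_like(pos)
        np.add.at(disp, i, unit * push[:, None])
        np.add.at(disp, j, -unit * push[:, None])
        pos = pos + disp
    return None


def validate_realization(real: ClusterRealization) -> None:
    """Independent O(n^2) overlap and containment check; raises on failure."""
    spec = real.spec
    norms = np.linalg.norm(real.centers, axis=1)
    if np.any(norms > spec.r_bound - spec.r_np + 1e-9):
        raise PackingError("containment violated: a nanoparticle pokes out of the bound")
    if spec.n_np > 1:
        diff = real.centers[:, None, :] - real.centers[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        iu = np.triu_indices(spec.n_np, k=1)
        if np.min(dist[iu]) < 2.0 * spec.r_np - 1e-9:
            raise PackingError("overlap detected between nanoparticles")


def radial_gold_fraction(
    real: ClusterRealization,
    n_shells: int,
    n_samples: int,
    seed: int,
) -> RadialGoldProfile:
    """Monte Carlo gold volume fraction in concentric shells of the bound.

    Uniform points are thrown in the bounding sphere; a point counts as
    gold when it lies within ``r_np`` of any nanoparticle center.  Near
    the surface the fraction drops below the interior plateau because
    whole nanoparticles must fit inside the bound.
    """
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 10000 for a usable estimate")
    spec = real.spec
    rng = np.random.default_rng(seed)
    pts = _uniform_in_ball(rng, n_samples, spec.r_bound)
    tree = cKDTree(real.centers)
    dist, _ = tree.query(pts, k=1)
    in_gold = dist <= spec.r_np
    edges = np.linspace(0.0, spec.r_bound, n_shells + 1)
    shell_idx = np.clip(
        np.searchsorted(edges, np.linalg.norm(pts, axis=1), side="right") - 1,
        0,
        n_shells - 1,
    )
    counts = np.bincount(shell_idx, minlength=n_shells)
    if np.any(counts == 0):
        empty = int(np.argmax(counts == 0))
        raise EstimationError(f"shell {empty} received zero samples")
    hits = np.bincount(shell_idx, weights=in_gold.astype(float), minlength=n_shells)
    return RadialGoldProfile(
        shell_edges=edges, fraction=hits / counts, n_samples=counts
    )


def two_shell_equivalent(
    spec: ClusterSpec, shell_thickness: float | None = None
) -> TwoShellMixSpec:
    """Two-shell mixture conserving the cluster's total gold mass.

    The outer shell (thickness ``shell_thickness``, default ``2*r_np``,
    the scale of the depleted surface layer) is pure water; all gold is
    concentrated in the inner core, whose density follows from mass
    balance.  As the thickness tends to 0 the core density tends to the
    homogeneous :func:`mixture_density`.
    """
    if shell_thickness is None:
        shell_thickness = 2.0 * spec.r_np
    if not (0 < shell_thickness < spec.r_bound):
        raise ValueError(
            f"shell_thickness must be in (0, r_bound), got {shell_thickness}"
        )
    r_inner = spec.r_bound - shell_thickness
    v_gold = spec.n_np * spec.r_np**3  # in units of (4/3)pi nm^3
    f_inner = v_gold / r_inner**3
    if f_inner > 1.0:
        raise InfeasibleSpecError(
            f"core gold fraction {f_inner:.3f} > 1: shell too thick to hold the gold"
        )
    rho_inner = f_inner * spec.rho_gold + (1.0 - f_inner) * spec.rho_water
    return TwoShellMixSpec(
        r_inner=r_inner,
        r_outer=spec.r_bound,
        rho_inner=rho_inner,
        rho_outer=spec.rho_water,
    )


def write_cluster(real: ClusterRealization, path: str | Path) -> None:
    """Write centers as CSV (x_nm, y_nm, z_nm) with a YAML spec sidecar."""
    import pandas as pd

    path = Path(path)
    df = pd.DataFrame(real.centers, columns=["x_nm", "y_nm", "z_nm"])
    df.to_csv(path, index=False, float_format="%.17g")
    meta = dataclasses.asdict(real.spec)
    meta["seed"] = real.seed
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))


def read_cluster(path: str | Path) -> ClusterRealization:
    """Read a realization written by :func:`write_cluster`."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    meta = yaml.safe_load(sidecar.read_text())
    seed = meta.pop("seed")
    spec = ClusterSpec(**meta)
    return ClusterRealization(
        spec=spec, centers=df[["x_nm", "y_nm", "z_nm"]].to_numpy(), seed=seed
    )
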