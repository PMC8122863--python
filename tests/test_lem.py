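"""LEM core: S1/S2, I1/I2 quadrature vs Monte Carlo, lesions, SEF, %Diff."""

import numpy as np
import pytest

from nanolem.geometry import CellGeometry, Region, region_volume
from nanolem.lem import (
    CellLineParams,
    compute_i1,
    compute_i2,
    def_profile,
    lethal_lesions,
    percent_diff,
    s1_profile,
    s2_profile,
    sef,
)
from nanolem.rdd import RadialDoseDistribution, RadialGrid, make_radial_grid

FOUR_PI = 4.0 * np.pi


def uniform_rdd(dose_value: float, r_max: float = 1e6) -> RadialDoseDistribution:
    """Uniform dose field from (almost) zero out to r_max."""
    edges = np.concatenate([[1e-6], np.linspace(1.0, r_max, 2001)])
    return RadialDoseDistribution(
        grid=RadialGrid(edges=edges),
        dose=np.full(edges.size - 1, dose_value),
        rel_err=np.zeros(edges.size - 1),
    )


def _sample_region(rng, geom, region, n):
    """Uniform points in a region, in the source frame (source at origin)."""
    region = Region(region)
    R = geom.r_nucleus if region is Region.NUCLEUS else geom.r_cell
    pts = np.empty((0, 3))
    while pts.shape[0] < n:
        cand = rng.uniform(-R, R, size=(2 * n, 3))
        keep = np.linalg.norm(cand, axis=1) <= R
        if region is Region.CYTOPLASM:
            keep &= np.linalg.norm(cand, axis=1) >= geom.r_nucleus
        pts = np.vstack([pts, cand[keep]])
    pts = pts[:n]
    pts[:, 2] += geom.d  # region center sits at distance d from the source
    return pts


def _mc_integral(rdd, geom, region, n, rng, power=1):
    """Monte Carlo volume integral of dose^power over the region."""
    pts = _sample_region(rng, geom, region, n)
    r = np.linalg.norm(pts, axis=1)
    idx = np.searchsorted(rdd.grid.edges, r, side="right") - 1
    vals = np.zeros(r.size)
    inside = (idx >= 0) & (idx < rdd.grid.n_bins)
    vals[inside] = rdd.dose[idx[inside]] ** power
    v = region_volume(geom, region)
    mean = vals.mean()
    se = vals.std(ddof=1) / np.sqrt(n)
    return v * mean, v * se


class TestSurfaceProfiles:
    def test_s1_uniform_dose(self):
        rdd = uniform_rdd(3.0, r_max=1e4)
        np.testing.assert_allclose(
            s1_profile(rdd), FOUR_PI * rdd.grid.mid**2 * 3.0, rtol=1e-12
        )

    def test_s1_constant_for_inverse_square(self):
        grid = make_radial_grid(70.0)
        dose = 5.0e4 / grid.mid**2
        rdd = RadialDoseDistribution(grid=grid, dose=dose, rel_err=np.zeros_like(dose))
        np.testing.assert_allclose(s1_profile(rdd), FOUR_PI * 5.0e4, rtol=1e-12)

    def test_s2_s1_algebraic_identity(self, noisy_pair_70):
        cluster = noisy_pair_70[0]
        s1 = s1_profile(cluster)
        s2 = s2_profile(cluster)
        np.testing.assert_allclose(
            s2 * FOUR_PI * cluster.grid.mid**2, s1**2, rtol=1e-12
        )

    def test_pdiff_s1_equals_pdiff_dose(self, noisefree_pair_70):
        cluster, mixnp, _ = noisefree_pair_70
        # The 4*pi*r^2 factor cancels in the ratio; compare with an
        # absolute floor since far-field differences underflow to ~0.
        np.testing.assert_allclose(
            percent_diff(s1_profile(mixnp), s1_profile(cluster)),
            percent_diff(mixnp.dose, cluster.dose),
            rtol=1e-9,
            atol=1e-9,
        )

    def test_pdiff_s2_from_dose_ratio(self):
        # A per-bin dose ratio (1 + delta) gives an S2 difference of
        # 100*((1+delta)^2 - 1): the 42% -> 102% pairing.
        assert 100.0 * (1.42**2 - 1.0) == pytest.approx(101.64)


class TestVolumeIntegrals:
    def test_uniform_dose_reduces_to_volume(self):
        rdd = uniform_rdd(2.5)
        geom = CellGeometry.from_um(15, 7, d_um=20)
        for region in Region:
            v = region_volume(geom, region)
            assert compute_i1(rdd, geom, region) == pytest.approx(2.5 * v, rel=1e-9)
            assert compute_i2(rdd, geom, region) == pytest.approx(
                2.5**2 * v, rel=1e-9
            )

    def test_zero_dose_gives_zero(self):
        rdd = uniform_rdd(0.0)
        geom = CellGeometry.from_um(15, 7, d_um=20)
        assert compute_i1(rdd, geom, Region.NUCLEUS) == 0.0
        assert compute_i2(rdd, geom, Region.NUCLEUS) == 0.0

    def test_additivity_cell_is_nucleus_plus_cytoplasm(self, noisy_pair_70):
        cluster = noisy_pair_70[0]
        geom = CellGeometry.from_um(15, 7, d_um=11)
        i1_cell = compute_i1(cluster, geom, Region.CELL)
        i1_parts = compute_i1(cluster, geom, Region.NUCLEUS) + compute_i1(
            cluster, geom, Region.CYTOPLASM
        )
        assert i1_cell == pytest.approx(i1_parts, rel=1e-12)

    def test_scale_covariance(self, noisy_pair_70):
        cluster, mixnp, _ = noisy_pair_70
        geom = CellGeometry.from_um(15, 7, d_um=12)
        k = 7.5
        i1 = compute_i1(cluster, geom, Region.CYTOPLASM)
        i2 = compute_i2(cluster, geom, Region.CYTOPLASM)
        assert compute_i1(cluster.scaled(k), geom, Region.CYTOPLASM) == pytest.approx(
            k * i1, rel=1e-12
        )
        assert compute_i2(cluster.scaled(k), geom, Region.CYTOPLASM) == pytest.approx(
            k**2 * i2, rel=1e-12
        )
        # DEF and %Diff are scale-invariant
        before = percent_diff(
            compute_i1(mixnp, geom, Region.CYTOPLASM), i1
        )
        after = percent_diff(
            compute_i1(mixnp.scaled(k), geom, Region.CYTOPLASM),
            compute_i1(cluster.scaled(k), geom, Region.CYTOPLASM),
        )
        assert after == pytest.approx(before, rel=1e-9)

    def test_inverse_square_nucleus_against_mc_oracle(self, rng):
        grid = make_radial_grid(70.0)
        dose = 1.0e4 / grid.mid**2
        rdd = RadialDoseDistribution(grid=grid, dose=dose, rel_err=np.zeros_like(dose))
        geom = CellGeometry.from_um(15, 7, d_um=20)
        i1 = compute_i1(rdd, geom, Region.NUCLEUS)
        mc, se = _mc_integral(rdd, geom, Region.NUCLEUS, 1_000_000, rng)
        assert abs(i1 - mc) < 3 * se

    def test_randomized_cases_against_mc_oracle(self, rng):
        # Randomized (RDD, geometry, region) cases: closed-form quadrature
        # must agree with uniform-point volume sampling within 3 sigma.
        n_cases = 20
        grid = make_radial_grid(70.0)
        for case in range(n_cases):
            dose = rng.uniform(0.5, 2.0) * 1e4 / grid.mid ** rng.uniform(1.0, 2.5)
            rdd = RadialDoseDistribution(
                grid=grid, dose=dose, rel_err=np.zeros_like(dose)
            )
            r_n = rng.uniform(3.0, 9.0)
            r_c = r_n + rng.uniform(2.0, 10.0)
            d = rng.uniform(r_n, 40.0)
            geom = CellGeometry.from_um(r_c, r_n, 0).at(d * 1000.0)
            region = [Region.NUCLEUS, Region.CYTOPLASM][case % 2]
            power = 1 if case % 3 else 2
            fn = compute_i1 if power == 1 else compute_i2
            analytic = fn(rdd, geom, region)
            mc, se = _mc_integral(rdd, geom, region, 1_000_000, rng, power=power)
            assert abs(analytic - mc) < 3 * se + 1e-12 * abs(analytic)


class TestLethalLesions:
    CL = CellLineParams(alpha=0.2, beta=0.05, dose_gy=2.0)

    def test_lq_baseline_without_enhancement(self):
        assert lethal_lesions(0.0, 0.0, 1.0, self.CL) == pytest.approx(
            0.2 * 2 + 0.05 * 4
        )

    def test_uniform_extra_dose_exact_lq_shift(self):
        # I1 = d0*V, I2 = d0^2*V must give alpha*(D+d0) + beta*(D+d0)^2:
        # the decisive consistency check of the reconstruction.
        a, b, D = self.CL.alpha, self.CL.beta, self.CL.dose_gy
        for d0 in (0.1, 1.0, 3.7):
            for v in (1.0, 1e12):
                n = lethal_lesions(d0 * v, d0**2 * v, v, self.CL)
                assert n == pytest.approx(a * (D + d0) + b * (D + d0) ** 2, rel=1e-12)

    def test_worked_example(self):
        assert lethal_lesions(1.0, 1.5, 1.0, self.CL) == pytest.approx(1.075)

    def test_uniform_rdd_through_full_chain(self):
        # End-to-end: quadrature + reconstruction jointly reproduce the
        # closed-form LQ shift to 1e-9 relative.
        d0 = 0.8
        rdd = uniform_rdd(d0)
        geom = CellGeometry.from_um(15, 7, d_um=18)
        a, b, D = self.CL.alpha, self.CL.beta, self.CL.dose_gy
        for region in Region:
            v = region_volume(geom, region)
            n = lethal_lesions(
                compute_i1(rdd, geom, region),
                compute_i2(rdd, geom, region),
                v,
                self.CL,
            )
            assert n == pytest.approx(a * (D + d0) + b * (D + d0) ** 2, rel=1e-9)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            lethal_lesions(1.0, 1.0, 0.0, self.CL)

    def test_enhancement_never_reduces_lesions(self):
        base = lethal_lesions(0.0, 0.0, 1.0, self.CL)
        assert lethal_lesions(0.5, 0.2, 1.0, self.CL) >= base


class TestSef:
    CL = CellLineParams(alpha=0.2, beta=0.05, dose_gy=2.0)

    def test_zero_enhancement(self):
        assert sef(0.0, 1.0, self.CL) == 0.0

    def test_worked_example(self):
        assert sef(1.0, 1.0, self.CL) == pytest.approx(2.0 / 3.0, rel=1e-4)

    def test_pure_alpha_limit_is_mean_extra_over_macro_dose(self):
        cl = CellLineParams(alpha=0.3, beta=0.0, dose_gy=2.0)
        assert sef(5.0, 10.0, cl) == pytest.approx(5.0 / (2.0 * 10.0), rel=1e-12)

    def test_zero_macro_dose_rejected(self):
        with pytest.raises(ValueError):
            sef(1.0, 1.0, CellLineParams(alpha=0.2, beta=0.05, dose_gy=0.0))

    def test_matches_i2_neglected_lesion_excess(self):
        cl = self.CL
        i1, v = 3.0, 7.0
        base = cl.alpha * cl.dose_gy + cl.beta * cl.dose_gy**2
        excess = (lethal_lesions(i1, 0.0, v, cl) - base) / base
        assert sef(i1, v, cl) == pytest.approx(excess, rel=1e-12)


class TestI2Dominance:
    def test_i2_term_negligible_at_default_scale(self, noisy_pair_70):
        # With Gy-scale near-surface doses the quadratic enhancement term
        # is orders of magnitude below the linear one.
        cluster = noisy_pair_70[0]
        cl = CellLineParams()
        geom = CellGeometry.from_um(15, 7, d_um=12)
        for region in (Region.NUCLEUS, Region.CYTOPLASM):
            i1 = compute_i1(cluster, geom, region)
            i2 = compute_i2(cluster, geom, region)
            linear = (cl.alpha + 2 * cl.beta * cl.dose_gy) * i1
            quadratic = cl.beta * i2
            assert quadratic / linear < 1e-2


class TestDefAndPercentDiff:
    def test_identical_rdds_give_unit_def(self, noisy_pair_70):
        cluster = noisy_pair_70[0]
        np.testing.assert_allclose(def_profile(cluster, cluster), 1.0)

    def test_linearity(self, noisy_pair_70):
        cluster = noisy_pair_70[0]
        np.testing.assert_allclose(
            def_profile(cluster.scaled(2.0), cluster), 2.0, rtol=1e-12
        )

    def test_zero_reference_yields_nan_marker(self):
        grid = RadialGrid(edges=np.array([1.0, 2.0, 3.0]))
        ref = RadialDoseDistribution(
            grid=grid, dose=np.array([0.0, 1.0]), rel_err=np.zeros(2)
        )
        test = RadialDoseDistribution(
            grid=grid, dose=np.array([1.0, 2.0]), rel_err=np.zeros(2)
        )
        out = def_profile(test, ref)
        assert np.isnan(out[0]) and out[1] == 2.0

    def test_grid_mismatch_rejected(self, noisy_pair_70):
        cluster = noisy_pair_70[0]
        grid = RadialGrid(edges=np.array([1.0, 2.0]))
        other = RadialDoseDistribution(
            grid=grid, dose=np.array([1.0]), rel_err=np.zeros(1)
        )
        with pytest.raises(ValueError):
            def_profile(cluster, other)

    def test_percent_diff_values_and_sign(self):
        assert percent_diff(1.0, 1.0) == 0.0
        assert percent_diff(1.42, 1.0) == pytest.approx(42.0)
        assert percent_diff(1.0, 2.0) == pytest.approx(-50.0)
        assert np.isnan(percent_diff(1.0, 0.0))

    def test_percent_diff_vectorized(self):
        out = percent_diff(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 0.0]))
        np.testing.assert_allclose(out[:2], [-50.0, 0.0])
        assert np.isnan(out[2])
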