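# Methods

## Scope and model

`nanolem` implements the biological stage of a multiscale
nanodosimetry calculation and a synthetic stand-in for its physical
stage.  The physical stage proper — condensed-history and
track-structure Monte Carlo transport of a clinical 6 MV beam through
phantom, cluster and water — is out of scope; its *outputs* (radial
dose distributions, escape-electron spectra, dose enhancement factors)
are emulated by a calibrated generator so the biological mathematics
can be exercised and tested at desk scale.  The radiation-chemistry
stage (radical production) is likewise out of scope.

The cell is two concentric spheres: nucleus (r_n, default 7 µm) and
cell (r_c, default 15 µm); the cytoplasm is their difference.  The
dose source (an activated nanoparticle cluster or its homogeneous
mixture surrogate) is treated as a point-centered, spherically
symmetric field: its finite radius enters only through the inner edge
of the radial grid and through placement-validity flags.  Angular
dependence of the field is neglected — the cluster has no preferred
orientation relative to the cell or the beam.

### Lethal lesions and SEF

With linear-quadratic coefficients α (Gy⁻¹), β (Gy⁻²) and macroscopic
dose D (Gy), the local-effect ansatz N = (1/V)∫[α·D_loc + β·D_loc²]dV
with D_loc = D + d(r) expands exactly to

    N = αD + βD² + (α·I₁ + β·I₂ + 2βD·I₁)/V ,
    I₁ = ∫ d(r) dV ,   I₂ = ∫ d(r)² dV  (over the sensitive volume V).

This expansion is the unique form consistent with the ansatz; the test
suite proves it by feeding a uniform extra dose d₀, which must return
α(D+d₀) + β(D+d₀)² to 1e-9 relative — jointly validating the formula
and the quadrature.  Neglecting the I₂ term (orders of magnitude below
I₁ at Gy-scale doses; asserted < 1e-2 in the tests), the relative
excess of N over the LQ baseline defines the sensitizer enhancement
factor SEF = I₁(α + 2βD)/(V(αD + βD²)).

Default cell-line parameters (α = 0.2 Gy⁻¹, β = 0.05 Gy⁻², D = 2 Gy)
are generic configuration values, not measurements of a specific line;
every result table records the parameters used.

### Exact solid-angle quadrature

Under spherical symmetry, I₁ = Σ_b D_b ∫_b Ω(r) r² dr where Ω(r) is
the solid angle of the sphere of radius r about the source that lies
inside the region.  For a target ball of radius R at center distance
d, Ω is 4π (r ≤ R−d), 0 (r ≥ d+R or r ≤ d−R), and otherwise the
spherical cap 2π(1 − (r²+d²−R²)/(2rd)).  On the cap regime, Ω(r)r² is
a polynomial in r, so each bin integral is evaluated from the
antiderivative, splitting bins at regime boundaries — no numerical
quadrature anywhere.  The completeness identity ∫₀^{d+R} Ω r² dr =
(4/3)πR³, checked to 1e-9 relative over randomized geometries, is the
load-bearing correctness guarantee.  Degenerate cases: d = 0 is
handled by the full/zero regimes alone (the cap branch is empty);
tangency radii take the continuous limit.  Dose is piecewise constant
per bin (matching how Monte Carlo scorers bin dose) and zero beyond
the last grid edge — the default grid extends to 1 mm, far past the
largest source–cell distance (≈ 55 µm), so truncation is nil.
Internal lengths are nm throughout; the µm-scale interface converts at
the boundary.

### Position convention

The source offset `d` is measured from the *cell center*, scanned over
[7, 40] µm in 0.05 µm steps by default.  The printed landmarks only
cohere under this convention (scan floor 7 µm = nucleus radius;
cytoplasm difference peak at 15 µm = cell radius).  The alternative
reading — distance from the nucleus surface — is available as a config
toggle (`d_from_nucleus_surface`), which offsets the scan by r_n; the
convention used is recorded in the run manifest.  Placements with
d < r_n are rejected (flagged rows with NaN values); membrane-spanning
placements (|d − r_c| < source radius) are computed but flagged, and
summaries report the maxima both with and without them, because the
largest cytoplasm differences occur exactly there.

## Synthetic data generator

### What it emulates

* **WNP baseline**: dose ∝ 1/r² (geometric falloff of a point-like
  electron source).
* **Cluster enhancement**: DEF(r) = 1 + (DEF_max − 1)·exp(−x/L) with
  DEF_max = 20 and decay length L = 1 µm by default, where x is the
  distance beyond the first scoring bin.  The surface peak value
  matches megavoltage activation of gold; the micrometre decay scale
  reflects that the enhancement is carried by few-keV-and-up secondary
  electrons whose ranges are micrometres — dose must be scored far
  from the source precisely because the enhanced field extends far.
  A sub-100-nm decay would confine the enhancement to the immediate
  surface, contradicting the millimetre-scale scoring the enhanced
  fields require.  An optional sinusoidal "waviness" modulation
  (default off) mimics the structure imprinted by discrete Auger and
  photoelectron energies.
* **Mixture excess**: the MixNP dose exceeds the cluster dose by
  δ(x) = δ₀·exp(−x/λ) with δ₀ = 0.42/0.57/0.62 for the 70/250/500 nm
  classes and λ fixed so δ = 0.05 at 15/60/50 nm beyond the surface.
  These endpoints are the calibration targets; the exponential form
  between them is this package's choice (the simplest curve through
  the pinned endpoints with the correct far-field limit).
* **Binning**: the published scorer schedule — 1 nm bins near the
  source, widening through 10/100/1000/10⁴ nm sections out to 1 mm
  (the 500 nm class has no 10 nm section).  Non-canonical source radii
  scale the 70 nm schedule proportionally.
* **Noise**: independent multiplicative Gaussian per bin, truncated at
  zero.  Per-bin σ scales as the reciprocal square root of the
  expected scored energy (∝ dose·r²·Δr), normalized so the *worst* bin
  sits exactly at the configured level (default 2 %) — statistical
  uncertainty "below 2 % for all bins" means 2 % is the worst bin, and
  wide far-field bins collect many more events than 1-nm surface bins.
  The per-bin σ is stored in `rel_err`.
* **Anchoring**: the smooth DEF and excess profiles are evaluated at
  bin midpoints and anchored at the *first bin's midpoint*, so the
  first-bin DEF and excess equal their calibration values exactly; the
  5 % crossing shifts by at most half the first bin width (0.5 nm)
  relative to a surface-anchored reading.
* **Escape spectra**: first energy bin centered at 0.1 keV (width
  configurable, default 0.2 keV); the cluster spectrum places 10 % of
  electrons in the first bin (a chosen baseline — only the
  MixNP/cluster *excess* of 42/77/97 % and the >350 keV tail fractions
  of 3.7/6.7/8.6 % are calibrated), an exponential bulk (scale 60 keV)
  up to 350 keV, and a truncated exponential tail (scale 800 keV) to
  6 MeV.  350 keV is an explicit bin edge so tail fractions are exact.
* **Range–energy kernel** (optional, qualitative only): R(E) = a·E^b
  with a = 40 nm, b = 1.7 (E in keV); each electron deposits uniformly
  per unit path over [R_src, R_src + R(E)], renormalized to the part
  of the track inside the grid so total deposited energy equals the
  spectrum energy times the configured absorbed fraction exactly.

### What it does not emulate

No cross sections, no Auger cascade physics, no phase-space recycling,
no beam model, no inter-bin dose correlations, no electron transport.
The generated difference profiles share the *endpoints* of the real
ones, not their shapes; consequently the position-scan difference
curves reproduce the qualitative structure (peak at the membrane for
the cytoplasm, monotone decline for the nucleus, sub-1.6 % magnitudes)
but not bin-level detail.  In particular the cytoplasm %Diff(I₁) peak
sits a few tenths of a µm *inside* the membrane (at d ≈ r_c − r_src)
rather than exactly at r_c: with smooth exponential profiles, the
near-surface excess keeps its full 4π weighting until the source
reaches the membrane while the denominator still shrinks.  Tests
therefore locate the peak within 1 µm of the membrane rather than at a
single grid step.  Passing tests validate the biological-stage
mathematics and the calibrated statistical structure — they are not
evidence about any specific physical beam/cluster combination.

### Cluster packing

Nanoparticle placement is random sequential addition (uniform
proposals in the ball of radius r_bound − r_np) with a relaxation
fallback: the canonical gold volume fraction 0.333 sits close to the
RSA saturation limit (~0.38), so when RSA stalls, the remaining
spheres are seeded randomly and overlapping pairs are pushed apart
iteratively (with containment re-projection) until the hard-sphere
constraints hold.  Fractions above 0.38 fail fast.  Every realization
passes an independent O(n²) overlap/containment check before being
returned, and all randomness flows through explicit seeds.  The
relaxation fallback makes the sampled ensemble slightly non-RSA near
saturation; for the geometric observables used here (radial gold
fraction, depleted surface layer) this distinction is immaterial.

The two-shell mixture variant (water jacket of configurable thickness,
default 2·r_np — the scale of the depleted surface layer — around a
denser core) conserves total gold mass by construction to 1e-12
relative.

## Numerical and design choices

* Dose carries an arbitrary linear scale; a config scalar converts to
  Gy.  Ratios (DEF, %Diff) are scale-invariant, and the default
  surface dose is set to 2 Gy in the first cluster bin so that lesion
  counts and SEF are on a physically sensible scale.
* %Diff(X) = (X_mix − X_cluster)·100/X_cluster; negative means the
  cluster exceeds the mixture; a zero denominator yields NaN, never an
  exception.
* Bin midpoints are arithmetic means; bins are narrowest (1 nm) where
  the dose varies fastest.
* Problem sizes: position scans use 661 positions × ~570–770 bins per
  size class, evaluated with closed-form vectorized quadrature (the
  full three-class study runs in seconds); Monte Carlo oracles in the
  tests use 10⁶ points per case.
* Determinism: every stochastic operation takes an explicit seed;
  paired RDDs draw three independent child streams from one seed (the
  curves stand in for independent simulation campaigns); study runs
  write a manifest with the config hash and seeds.

## Known limitations

* The synthetic generator's functional forms are convenient, not
  physical; only their calibration endpoints are anchored to reported
  megavoltage gold-cluster behavior.
* The formalism assumes the sensitive volume lies entirely outside the
  source sphere (the cluster is biologically inert); sources
  overlapping a region trigger a warning, and nanoparticles inside the
  nucleus require a different formalism altogether.
* Spherical cells, nuclei and clusters only.  Arbitrary cluster shapes
  can in principle be composed by superposition of spherical sources,
  but no such composition layer is provided.
* The linear-quadratic response is taken as exact over the local dose
  range; no saturation or track-structure corrections.
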