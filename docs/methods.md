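# Methods

## The phantom model

The phantom is the 1-skeleton of a centroidal Voronoi tessellation (CVT)
inside a 4 cm cube: generating points are drawn by Poisson-disk dart
throwing (exclusion radius 0.75·(V/n)^⅓, a standard feasibility margin
that keeps random sequential adsorption far from saturation), relaxed by
Lloyd's algorithm, and the segments where three or more Voronoi cells meet
become printable branches. Branch radii are independent uniform draws over
half the printed diameter band, 0.2–0.4 mm. Node caps equal the largest
incident branch radius, so joints are the plain union bulge where several
branches meet — up to about two branch diameters (~1.6 mm) across, which
matches the printed phantom this geometry emulates. A larger spherical
joint primitive was rejected: at a cap of twice the incident radius the
joints dominate the resin mass, exceed the 1.6 mm envelope once density
tuning rescales them, and push the phantom's WEPL spread outside the
column-model band the geometry itself predicts.

**Number of generating points.** The printed design values overdetermine
n. A bulk density of 0.237 g/cm³ in resin of 1.11 g/cm³ needs
64·0.237/1.11 = 13.7 cm³ of material; uniform 0.4–0.8 mm branches carry
π·E[r²] ≈ 2.9·10⁻³ cm² per cm, so the skeleton must total ≈ 4700 cm.
CVT skeleton length grows as n^⅔ and measures ≈ 4680 cm at n = 3000 in
the 4 cm cube (≈ 2275 cm at n = 1000, which would force ~22% oversized
branches after tuning). Default: `n_points = 3000`.

**Lloyd relaxation.** Cell centroids are estimated on a fixed uniform
Monte-Carlo sample (100 points per generator, ≥ 10⁵), making each sweep
exactly one k-means step on that sample; the quantization energy is then
provably non-increasing, which the tests assert. Default 30 sweeps or a
10⁻³ cm movement tolerance — texture statistics change negligibly beyond
that. Exact clipped-polytope centroids are unnecessary for phantom
texture.

**Clipping.** The tessellation is computed on the points plus their six
face reflections; the bisector of a point and its mirror is exactly the
cube face, so cells are clipped to the cube by construction and face/edge
segments of the cube appear naturally in the skeleton. Only the largest
connected component is kept — a disconnected fragment could not be
printed or supported.

## Voxelization and density tuning

The capsule/sphere union is rasterized on the 100³ grid of 0.4 mm voxels
(cube corner at the origin, beam along +z, 0-based indices, voxel-center
convention). For supersampling s > 1 each of the s³ sub-cells contributes
a first-order coverage weight clip(½ + (r − d)/h, 0, 1) instead of a
binary in/out vote: a 0.3 mm branch spans only ~3 sub-cells at s = 4,
where lattice-point counting has ~4% placement noise (worst case 13%)
while the coverage estimate is accurate to ~1%. s = 1 is the exact binary
center test and is what transport consumes (the printed object is
two-material, resin or air; the fractional grid is kept for mass
accounting, thresholded at 0.5 for transport). Air is 0.0012 g/cm³ —
negligible, but it keeps the mass accounting honest.

Density tuning applies one global multiplicative factor to all radii
(topology preserved) and bisects it against the voxel-grid density.
Because a point is inside the scaled union iff (distance/radius) ≤ scale,
a single distance-ratio field supports the whole bisection without
re-rasterizing; the stopping tolerance of 0.05% relative leaves margin
under the 0.1% design-error budget. Radii pushed outside the printable
band are reported (warning), not clamped, so the computational phantom
stays exactly the tuned geometry.

## Beam model

The pristine curve is a Bortfeld-type power-law build-up,
D₀(z) ∝ (R−z)^(1/p−1) + β(R−z)^(1/p) with 1/p = 0.565 from the
range–energy relation and β = 0.012 cm⁻¹ for fluence reduction,
cell-averaged analytically across each bin (the z → R singularity is
integrable) and convolved with a single Gaussian σ that lumps intrinsic
straggling and beamline energy spread. Water ranges default to 15.6 cm
(155 MeV) and 25.9 cm (200 MeV) from standard tables, but every headline
quantity depends only on the distal-edge shape, which is pinned by
calibrating σ against a measured pristine DFW (bisection, converging to
¼ of the 0.02 cm depth bin). A measured pristine curve can be supplied as
CSV instead. Depth-dose curves live on a uniform 0.02 cm grid throughout.

**Two width conventions, kept deliberately distinct.** For this curve
family the geometric 80–20% distal falloff measures 1.32 σ (an erfc edge
would measure 1.683 σ; both differ from the 1.13 σ bookkeeping constant
used in the published analysis chain this package reproduces).
`pdd_analysis` therefore exposes `DFW_SIGMA_FACTOR = 1.13` — used exactly
where that bookkeeping is reproduced — and `GAUSSIAN_EDGE_8020 = 1.683`
as clearly separate constants, and the quadrature-closure test converts
widths with the curve family's own measured ratio. A related published
inconsistency is reproduced as printed: 0.36 cm/1.13 = 3.19 mm, yet the
source chain uses σ_pristine = 3.13 mm at 200 MeV and obtains 2.86 mm for
the heterogeneity σ; the package reproduces 2.86 from the printed inputs
(4.24, 3.13) and does not attempt to resolve the rounding.

SOBP weights are non-negative least squares on a flat-plateau constraint
over the modulation width; the achieved central-90% flatness is reported
and warned about above 2%. The real beamline's modulation hardware is not
modeled, so no SOBP quantity is treated as a reproduction target.

## Transport: independent-ray range mixing

Rays run parallel to +z on a jittered 0.1 mm lateral grid (160 000 rays
over the 4 cm face; jitter avoids voxel-lattice aliasing, and the
axis-parallel geometry makes voxel traversal exact). Each ray's WEPL is
the column sum of voxel length × RSP, with RSP taken as the mass-density
ratio (resin 1.11, air 0.0012); the few-percent RSP error of real resin
only shifts the mean range, which cancels out of every falloff metric.
The transmitted curve is the ray-average of the pristine curve shifted
per ray by its WEPL minus the displaced-air equivalent, normalized to the
pristine maximum so its peak reads directly as the peak value. The slab
comparator applies the single shift thickness × density, leaving the
falloff width unchanged by construction.

**Declared approximation and its measured consequence.** Multiple Coulomb
scattering, nuclear interactions and ray crossing are neglected — the
same idealization as the binomial column model. This matters: in a full
Monte Carlo, lateral scattering mixes neighbouring columns before the
protons stop, averaging away part of the high-frequency WEPL variance.
The independent-ray model keeps all of it, so its falloff widths are
upper estimates. Measured at the default conditions (seed 7): WEPL spread
σ_w = 3.3–3.4 mm, at the top of the column-model band
[1.70, 3.40] mm for structure sizes between one branch and one joint
diameter; degraded DFW ≈ 0.47 cm at 155 MeV and ≈ 0.55 cm at 200 MeV,
about 0.03–0.07 cm wider than lateral-mixing transport gives for the same
voxel geometry; degraded 155 MeV peak ≈ 73%, inside the measured range.
Users needing MC-grade distal edges should export the voxel phantom
(.mhd) into a full transport code — that is the intended workflow this
fast model complements.

## The column model and its oracle

σ²(z) = (p − p²)·z·Δ treats a beam column as z/Δ independent segments of
size Δ, each resin with probability p. Following the published usage, p
is the bulk density in g/cm³ read as a dimensionless number (0.237), not
the volumetric fill fraction (0.214) — required to reproduce the printed
1.70/3.40 mm band. `binomial_column_oracle` verifies the closed form by
direct binomial simulation; the tests require agreement within 3 standard
errors across a (p, Δ) grid.

## What the generator does and does not emulate

Generated phantoms reproduce: the bulk density and its 0.1% tuning
tolerance, the printed branch-diameter band and joint envelope, the
open-cell connected morphology, and a WEPL heterogeneity inside the
column-model band. They do not reproduce: the exact (unpublished) point
count and radius distribution of any physical specimen, printer artifacts
(support-material residue, surface roughness, resin RSP ≠ density ratio),
anatomical airway branching, or lung motion. Passing tests therefore
demonstrate internal consistency of geometry → density → range mixing,
not dosimetric equivalence to any individual printed object.

## Numerical choices

* Depth grid 0.02 cm; pristine curves padded ≥ 4 cm (or 8 σ) past the
  range so degraded tails stay on-grid; shifts beyond the support are
  zero-padded with a warning.
* DFW crossings by linear interpolation, first crossing after the global
  maximum; an isotonic (non-increasing envelope) fallback for noisy tails
  sits behind `smooth=True`.
* Bisection tolerances: density 0.05% relative; σ calibration ¼ depth
  bin; radius-scale search bracket (0, 4].
* Voronoi node dedup at 10⁻⁹ cm; skeleton endpoints clamped to the cube
  to remove clipping round-off.
* Seeds: every stochastic step (sampling, Lloyd sample set, radius draws,
  ray jitter) derives from one integer seed via independent
  `numpy` `SeedSequence` streams; fixed seed ⇒ bit-identical artifacts.

## Known limitations

* Independent-ray transport overestimates distal widening for structure
  coarser than the lateral-scattering scale (see above) — its outputs are
  conservative upper estimates, not MC surrogates.
* The 100³ binary map under-resolves 0.4 mm branches (partial-volume
  aliasing); the density bookkeeping uses the fractional grid, but
  transport inherits the binary map's ~2% fill-fraction bias.
* Lloyd centroids are Monte-Carlo estimates; point positions carry
  ~10⁻³ cm sampling noise (irrelevant at 0.4 mm voxels).
* The SOBP builder is a generic flat-plateau optimizer, not a model of
  any specific modulation hardware.
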