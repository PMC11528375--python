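# Methods

This note documents the models and numerical choices behind `hippomorph`,
in the order the pipeline runs: trace rasterization → mask labeling → image
denoising → level-set evolution → signed-distance twin → surface mesh →
descriptors → agreement and cohort statistics → the synthetic generators
that stand in for patient data.

## Geometry conventions

All physical coordinates are millimetres; descriptor reports use cm, cm²
and cm³ to match clinical volumetry tables. Voxel `(i, j, k)` covers the
half-open cube `[i·s, (i+1)·s)` and its *center* sits at `(i + 0.5)·s` plus
the grid origin. Volumes are stored sagittally (slices along axis 0), and
indices are 0-based. A binary mask voxel is true iff its center lies inside
the traced region — no partial-volume weighting — which makes rasterization,
distance transforms and voxel-count volumes mutually consistent and
convergent as `s → 0`.

## Trace rasterization

Per-slice closed polygons (mm coordinates in the sagittal plane) are filled
with the even-odd (crossing-number) rule evaluated at voxel centers.
Even-odd is orientation-independent and well defined for accidentally
self-intersecting hand traces (these are filled, with a warning, rather
than rejected); polygons extending past the slice are clipped with a
warning. Left/right identity and rater are metadata carried with the
traces, never inferred from the image. The trace interchange format is a
small documented JSON schema
(`{patient, rater, side, slices: [{index, polygons: [[x, y], ...]}]}`);
proprietary ROI dialects are out of scope.

## Component labeling

The binarized trace volume is labeled by a watershed on the negated
internal Euclidean distance transform, seeded at distance maxima after
h-maxima suppression (h = 1 voxel) to avoid over-segmentation. Touching
blobs of comparable depth split along the surface equidistant from their
cores (verified to within one voxel of the analytic mid-plane for two
overlapping spheres); the largest component is flagged as the structure
candidate, so stray speckles never win.

## Denoising

Non-local means (patch radius 1, search radius 3, patch-mean weighting via
scikit-image's fast mode) with the filter strength tied to a robust noise
estimate: `sigma_hat = 1.4826 · MAD(Laplacian(I)) / sqrt(42)`, the median
absolute deviation of the 6-connected discrete Laplacian whose kernel has
squared-weight sum 42. Structure edges live in the tails the MAD ignores.
The default strength is `0.8 · sigma_hat`; a constant image is a fixed
point. On the standard noisy phantom (two-level 100/20 image, σ = 10) the
interior residual drops by >90 % while the half-max edge position moves
less than a voxel.

## Level-set evolution

The twin is evolved with a distance-regularized level-set formulation. In
voxel units, with φ negative inside:

    dφ/dt = μ · div(d_p(|∇φ|) ∇φ)                (distance regularization)
          + λ · δ_ε(φ) · div(g ∇φ/|∇φ|)          (edge-weighted length)
          + α · g · δ_ε(φ)                        (balloon / area)

`d_p` is the double-well potential derivative that drives `|∇φ| → 1` near
the interface without explicit re-distancing, and `δ_ε` is the smoothed
Dirac of width ε = 1.5 voxels. The edge-stopping map is

    g = 1 / (1 + (|∇(G_σ ∗ I)| / K)²),  σ = 0.5 mm,
    K = 0.1 × 99.5th-percentile gradient magnitude (overridable).

The gradient scale K makes g independent of the arbitrary intensity units:
without it, high-contrast images produce a several-voxel-wide g ≈ 0
plateau in which the balloon force dies and the front stalls short of the
edge. The strongest edges map to g ≈ 0.01; flat regions to g ≈ 1.

Defaults: μ = 0.2, λ = 5, α = −1.5 (negative = expanding balloon, suited to
inits at or inside the boundary), 250 iterations, narrow band 5 mm around
the initial interface (outside it the field stays the initial SDF). The
time step is 0.1: the diffusion bound (`dt·μ < 0.25`) is enforced at
construction, but on sharp synthetic edges the advective edge term is the
binding constraint, and dt = 0.1 keeps every update well below a voxel per
step. All parameters are exposed on `EvolutionParams`.

With 0 iterations the call returns the reinitialized signed distance of the
init unchanged. After a nonzero evolution the zero-sublevel set is
re-quantized to the voxel lattice and reinitialized, so every output is an
exact signed distance field; the sub-voxel interface position the PDE
carries (≲ a quarter voxel) is traded for an output with invariants that
hold by construction. The evolution is fully deterministic, and performed
in 3D (not per slice). On phantoms, an exact init on a clean image holds
Dice ≈ 1.0 over 200 iterations, an init eroded by 2 voxels on a noisy
(σ = 5) NLM-denoised image recovers Dice ≥ 0.95, and the front never leaves
a ±3 mm corridor around the initial interface.

## Signed distance and its discrete invariants

Reinitialization computes the exact Euclidean distance transform on both
phases with a half-voxel interface offset (a center adjacent to the
interface is half a voxel from it): `φ = −(d_in − s/2)` inside,
`d_out − s/2` outside. φ < 0 exactly on mask-true voxels and the operation
is idempotent to 1e-6 mm.

The continuum invariant `|∇φ| = 1` cannot hold pointwise on a voxel EDT:
interface voxels carry exact lattice kinks (values such as 2−√2, √2, √3
with one-sided differences). The distance-likeness check
(`sdf_band_fraction`) therefore evaluates the gradient of the lightly
smoothed field over the band |φ| ≤ 3 mm and asks that ≥ 99 % of band voxels
fall in [0.8, 1.2]; a scaled or binary field scores near 0.

## Surface extraction

Marching cubes at φ = 0 with linear interpolation, vertices mapped to the
voxel-center frame and oriented so the enclosed volume is positive. Two
numerical details matter at 0.5 mm:

* **Pre-smoothing.** Raw EDT fields are cone-like with lattice
  quantization; contouring them directly inflates the triangulated area by
  ~8 %. φ is Gaussian-smoothed by 0.6 voxels first (negligible effect on
  already-smooth fields).
* **Volume calibration.** Smoothing a distance field contracts convex
  interfaces (one mean-curvature-flow step), costing ~0.5 % volume. The
  extracted iso-level is bisected (up to ±1 voxel, 20 iterations, 0.1 %
  tolerance) so the mesh volume matches the voxel-count volume of the
  zero-sublevel set — the unbiased volume estimate the grid provides.

With both, phantom meshes land within 1 % of analytic volume and 2 % of
analytic area at 0.5 mm spacing, and mesh volume tracks voxel-count volume
by construction.

## Descriptors

**Inscribed sphere.** `r_in,max = max(−φ)` locates the deepest voxel; the
center is then refined on a sub-voxel grid (±1 voxel at s/4 steps) by
maximizing distance to the mesh vertices (KD-tree). The refinement is
needed because the SDF is cone-like at its apex — quadratic interpolation
is invalid there and the raw argmax under-reads by up to half a voxel
diagonal.

**Enclosing sphere.** Exact smallest enclosing ball by Welzl's randomized
incremental algorithm, unrolled over the ≤ 4 boundary support points, with
a seeded shuffle (deterministic) and convex-hull reduction for large vertex
sets. Verified against an exhaustive over-all-support-subsets reference on
seeded point clouds up to 250 points (1e-6 agreement).

**Sphericity** `S = r_in,max / r_cir,min`, clipped at 1 when the two radii,
which come from different discretizations (SDF vs mesh), cross by less than
2 %; a larger inversion raises an error.

**Corners and roundness.** The corner-based roundness needs a corner
decomposition the literature leaves open. A corner here is a connected,
locally cap-like surface patch whose maximum principal-curvature radius
`r(v) = 1/κ_max` does not exceed `r_in,max · 1.1`. "Cap-like" means both
curvatures are convex and comparable, `κ_min ≥ 0.3 · κ_max`: analytically a
cylinder wall has the same κ_max radius as an end cap, so a κ_max-only
criterion cannot separate a capsule's two caps from its wall; the elliptic
test does. Regions smaller than 5 % of the largest candidate region are
discarded as curvature noise, and if nothing qualifies the sharpest convex
vertex forms a single fallback region. `r_i` is the region-mean radius, and
`R = (1/N) Σ r_i / r_cir,min` — the circumscribed denominator as the
descriptor is defined here, with a config switch for the classical Wadell
convention (inscribed denominator).

Per-vertex curvatures come from integral measures over a geodesic-ball
neighborhood (radius 4.5 mean edge lengths, so the estimator is
scale-equivariant): mean curvature from the signed dihedral angles of the
enclosed edges, Gaussian curvature from the enclosed angle defects, both
divided by the enclosed area; principal curvatures via
`κ = H ± sqrt(H² − K)`. On near-umbilic patches the discriminant is pure
estimation noise and `H + |noise|` would bias κ_max upward, so whenever
`sqrt(H² − K) < 0.3·|H|` the point is treated as umbilic. A pointwise
quadric fit was evaluated first and rejected: on marching-cubes meshes its
κ_max carries a 10–30 % selection bias that no amount of Taubin smoothing
removes, while the integral estimator reads a sphere's radius to ~4 % and a
capsule cap's to ~2 %. The mesh is Taubin-smoothed (λ = 0.5, ν = −0.53,
10 iterations) before curvature estimation; the marching-cubes staircase
dominates κ otherwise.

**Principal axes and aspect ratio.** Directions are eigenvectors of the
interior voxel-center covariance; extents are projection ranges of the
*surface mesh* vertices along those directions (interior centers under-span
the solid by an amount that depends on surface orientation relative to the
lattice — exactly one voxel for axis-aligned flat faces, nearly zero for
curved surfaces — so no constant correction works for both). Extent-based
aspect ratio gives exactly c/a for an ellipsoid, which eigenvalue square
roots would not. Degenerate covariance falls back to the bounding box with
a warning.

**Volume-to-surface ratio.** Both `V/S` (cm) and `S/V` (cm⁻¹) are reported.
For a compact ~3 cm³ structure `V/S` is a few tenths of a cm, while
published hippocampus tables print values near 8 "cm" — dimensionally
consistent with `S/V`, not `V/S`. The definition in the source literature is
ambiguous; reporting both sidesteps the guess and flags the discrepancy.

## Inter-rater agreement

The mismatch between two positive measurements is
`|m1 − m2| / ((m1 + m2)/2) × 100` — symmetric, zero iff equal, and
scale-invariant. This pairwise-mean denominator reproduces four of the
published per-descriptor values exactly (3.03, 7.14, 5.33, 3.23 %); the
printed sphericity (16.78 %) and volume-to-surface (8.47 %) figures deviate
slightly from it on the rounded table means (16.67 and 8.45 under this
formula), and the baseline 13 % (means 3.4, 3.9) is 13.7 % — the formula is
kept rather than fitting per-row denominators. A pair *matches* when its
mismatch is within the tolerance (default ±3 %); match rates are reported
rounded to integer percent. The tuning protocol (flag → revise →
re-measure) is implemented as an auditable loop with a pluggable revision
callback, since the real revision step is human re-tracing; it stops when
the summary mismatch reaches the threshold or at the round limit, keeping
the full per-round audit trail. Rater calibration is OLS of rater 2 on
rater 1 with the percentage error `E = 100·b/x̄` (intercept over the pooled
two-rater mean).

## Cohort statistics

* **Sample size**: `n = N·Z²·p·q / (e²(N−1) + Z²·p·q)`; monotone decreasing
  in e, increasing in Z and (for p ≤ ½) in p·q; `n ≤ N`.
* **Normality**: one-sample KS against a normal with sample-estimated mean
  and SD, standard asymptotic p. Estimating the parameters from the same
  sample makes this strongly conservative (the Lilliefors effect — the null
  rejection rate at α = 0.05 is essentially zero); the implementation
  matches the common applied usage and logs the caveat. Tests assert
  conservatism under the null and near-certain rejection of a clearly
  non-normal alternative at large n.
* **t-tests**: two-tailed, Welch by default (Student's pooled variant
  available), from raw samples or from published (mean, SD, n) summaries;
  the two forms agree to 1e-9 on raw-data summaries. Cross-study
  comparisons use the two-rater hippocampus count (n = 126) for one's own
  cohort — with the published Turkey summary (3.81 ± 0.49, n = 302) this is
  the convention that reproduces the printed t = 7.11. Hemisphere
  comparisons treat sides as independent samples by default (a paired path
  is available through the pair table).
* **Volume–age fits**: degree-2 polynomials by OLS or WLS. `wls_residual`
  uses weights `1/(|OLS residual| + ε)` — the literal
  "weights = residuals" reading would up-weight outliers, so it is inverted;
  `wls_literal` keeps the literal reading for fidelity experiments;
  `wls_binned` weights each record by its 5-year age-bin mean volume. R² is
  computed on the weighted fit; the vertex (peak age/volume) is flagged
  undefined when the quadratic coefficient vanishes.
* **No multiple-testing correction** is applied anywhere; reports say so
  explicitly.
* **Low-volume probe**: records at or below per-rater volume thresholds are
  flagged, and each other descriptor reports the flagged subgroup's mean
  percentile within the full distribution — below 50 means the small
  structures sit left of the median for that descriptor.

## Synthetic generators

**Phantoms** voxelize analytic solids (sphere; triaxial ellipsoid with
exact elliptic-integral surface area; capsule; bent tube along a spline —
the seahorse-like smoke-test shape, which carries no closed-form truth)
under a rigid pose, emitting a two-level intensity image (inside 100,
outside 20, Gaussian noise σ = 5 by default) and the center-inside mask.
The two-level contrast gives the NLM + level-set stages a strong but
controlled edge; real MRI physics (bias fields, partial volume, Rician
noise, anatomical texture) is deliberately not emulated, so pipeline tests
demonstrate correctness of the machinery, not clinical robustness.

**Cohorts** draw one record per patient × hemisphere × rater. Rater-1
volume follows an inverted-U quadratic in age through the peak
(55 y, 3.7 cm³) and the late-life anchor (90 y, 1.7 cm³) — one quadratic
cannot also match the reported young-adult volumes, so the curve at age 18
is whatever the quadratic dictates (~2.5 cm³) — plus *centered* sex
(+0.125 cm³ male, applied as `offset·(male − male_fraction)`) and
hemisphere (+0.325 cm³ right, `offset·(right − ½)`) effects and Gaussian
residual noise (0.5 cm³), floored at 0.5 cm³. Centering makes the quadratic
the population mean curve of the pooled volume-age scatter, which is what
such scatter plots show; group differences still equal the configured
offsets. Ages are uniform on [18, 95]; the male fraction is 26/63. Rater 2
applies the linear calibration `0.981·v1 + 0.156` plus noise whose spread
is derived, not hand-tuned: for `y = βx + ε`,
`R² = β²σx²/(β²σx² + σε²)`, so `σε = |β|·σx·sqrt(1/R² − 1)` with σx the
analytic rater-1 SD (quadratic-age variance from uniform moments + Bernoulli
offset terms + residual variance) and target R² = 0.93. Non-volume
descriptors are drawn around the study's descriptor panel means
(AR 0.28, D 4.03 cm, R 0.75, S 0.12, V/S 7.93) with small spreads, a
per-descriptor rater-2 shift matching the reported rater differences, and
volume couplings (diameter and V/S rise with volume, roundness falls) that
mirror the reported shrinkage pattern; aspect ratio and sphericity are left
uncoupled. Everything is reproducible from one seed.

Under these conditions the residual volume spread (0.5 cm³) sits between
the tight spread implied by the post-tuning rater agreement and the looser
one implied by the reported volume-age fit quality (the two are not
mutually consistent); the pooled cross-sectional SD comes out ≈0.9 cm³.
One consequence: at 63 hippocampi per side the hemisphere t-test has ~50 %
power at the configured 0.325 cm³ effect, so power checks run at 500
patients per replicate, where power is ≈1.

## Problem sizes and tolerances in the test suite

Phantom grids are 48³–104³ at 0.5 mm (the ellipsoid truth oracle runs a
dense EDT at 0.25 mm); level-set runs use 200–250 iterations; cohort
recovery uses 500 patients with 10 seeded replicates for the offset and R²
checks (averaging replicates puts the Monte-Carlo error well inside the
tolerance bands) and 200 replicates for power. Geometry tolerances follow
the discretization level: 1 % on phantom volumes, 2 % on areas, ±0.05 on
the dimensionless descriptors, 1e-6 on the enclosing-ball cross-check.

## Known limitations

* The evolution assumes near-isotropic voxels (it runs in voxel units of
  the mean spacing); strongly anisotropic acquisitions should be resampled
  first.
* Corner decomposition on noisy, genuinely lumpy anatomy has no ground
  truth; roundness values are convention-dependent (corner criterion,
  denominator) and should be compared only within one convention.
* The final twin's interface is quantized to the voxel lattice
  (half-voxel convention); descriptor accuracy is bounded by voxel size,
  not by the PDE.
* The cohort simulator reproduces the *statistical structure* of a manual
  volumetry study, not anatomy; passing recovery tests shows the statistics
  are implemented correctly, not that real cohorts behave this way.
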