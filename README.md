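# hippomorph

3D morphometry of the hippocampus from manually traced brain MRI, built
around a level-set "digital twin": the segmented structure is represented as
a signed distance field φ(x) (negative inside, mm units) whose zero level
set is the anatomical surface, and every morphological descriptor is
computed from that representation with computational-geometry tools.

The package is aimed at neuroimaging groups running manual-volumetry
studies: two raters trace a structure slice by slice, the traces are
rasterized to masks, refined against the (denoised) image by a
distance-regularized level-set evolution, and the resulting twin yields a
standard descriptor panel. The same code base carries the study-level
statistics such projects need — inter-rater mismatch and tuning, rater
calibration, sample-size arithmetic, normality screening, t-tests against
published cohort summaries, and quadratic volume-vs-age fits.

## Descriptors

For one structure with maximum inscribed sphere radius `r_in,max` and
minimum circumscribed sphere radius `r_cir,min` (exact smallest enclosing
ball of the surface):

| descriptor | definition | units |
|---|---|---|
| volume `V` | signed tetrahedron sum over the closed surface mesh | cm³ |
| surface area `S_area` | triangle-area sum | cm² |
| diameter `D` | `2 · r_cir,min` — diameter of the smallest sphere containing the shape | cm |
| sphericity `S` | `r_in,max / r_cir,min` (1 for a sphere) | — |
| roundness `R` | `(1/N) Σ r_i / r_cir,min` over the N corner regions, `r_i` the corner curvature radius | — |
| aspect ratio `AR` | shortest / longest principal-axis extent | — |
| volume-to-surface | `V / S_area` (its reciprocal `S_area / V` is reported alongside) | cm |

Everything is exercised against voxelized phantoms (sphere, ellipsoid,
capsule, bent tube) with closed-form ground truth, and cohort statistics
against a seeded simulator with known generative parameters — no patient
data is required to validate the pipeline.

## Worked example

Build a noisy sphere phantom (r = 9.2 mm, 0.5 mm voxels, Gaussian noise
σ = 5 on a 100/20 two-level image), reconstruct the twin, and describe it:

```
$ hippomorph phantom make --family sphere --radius 9.2 --grid 48 \
      --noise-sigma 5 --seed 1 --out sph
$ hippomorph reconstruct run --image sph.nii.gz --mask sph_mask.nii.gz \
      --out twin.nii.gz --mesh twin.ply --iterations 50
$ hippomorph morph describe --twin twin.nii.gz --out desc.json
{
 "volume_cm3": 3.239407372857047,
 "surface_cm2": 10.718090392065156,
 "diameter_cm": 1.85960580138534,
 "sphericity": 0.9703728326788461,
 "roundness": 0.9507360483559254,
 "aspect_ratio": 1.0,
 "vs_ratio_cm": 0.3022373626607267,
 "sv_ratio_per_cm": 3.30865777545359
}
```

The analytic values for this sphere are V = 3.26 cm³, S_area = 10.64 cm²,
D = 1.84 cm, S = R = AR = 1 and V/S_area = r/3 = 0.307 cm; the
reconstruction lands within a few percent of each, the expected
discretization level at 0.5 mm voxels.

Simulate a 63-patient, two-rater cohort and compare the raters on volume:

```
$ hippomorph phantom cohort --n-patients 63 --seed 1 --out cohort.csv
$ hippomorph agree compare --table pairs.csv --tolerance 3
{
 "matched": 28, "total": 126, "match_rate_percent": 22,
 "regression": {"slope": 1.043, "intercept": -0.028, "r_squared": 0.929, ...}
}
$ hippomorph cohort samplesize --N 1724617 --Z 1.90 --p 0.035 --e 0.05
{"n_exact": 48.76974910031545, "n": 49}
```

28 of the 126 simulated volume pairs agree within ±3 % before any tuning,
and the rater-2-on-rater-1 regression recovers the configured calibration
(slope ≈ 1, R² ≈ 0.93). The sample-size line evaluates the
finite-population formula `n = N·Z²·p·q / (e²(N−1) + Z²·p·q)`.

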