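# Methods

This note documents the models, parameters and numerical choices behind
`petresponse`, and what the synthetic validation does and does not show.

## Coordinate and voxel conventions

All volumes live on regular axis-aligned grids.  Voxel indices are 0-based;
the world position of voxel *i* is `origin + (i + 0.5) * spacing` (voxel-
center convention), used consistently by the rasterizer, the delineation
sampler, the SUV_peak sphere and the NIfTI affines.  The default grid is
96×96×64 voxels at 4-mm isotropic spacing — a torso-like 38×38×26 cm field
of view at the spacing implied by the evaluability rule (a 3×3×3-voxel
block ≡ 1.728 mL forces 4-mm voxels).  Anisotropic spacing is supported
throughout but the reference thresholds assume 4 mm.

## Phantom model

A phantom is a uniform background (default 1.0 g/mL, a typical soft-tissue
SUV) plus ellipsoidal lesions of constant true SUV.  A voxel belongs to a
lesion iff its center lies inside the ellipsoid — no partial-voxel
weighting — matching the voxel-counting volume rule used downstream;
overlaps resolve to the maximum SUV, which is deterministic and
order-independent.  Image formation is rasterize → Gaussian blur →
additive noise:

* **Blur**: Gaussian with σ = FWHM / (2√(2 ln 2)) per axis, replicate
  boundary padding; default FWHM 4 mm, the modeled scanner resolution.
* **Noise**: additive zero-mean Gaussian in SUV units, clipped at zero,
  default σ = 0.1 SUV.  PET noise is Poisson-like in count space, but this
  pipeline operates purely in SUV space where no count model is available;
  additive Gaussian noise with σ well below lesion contrast is the
  standard desk-scale surrogate.  Phantom validation therefore says
  nothing about count-starved, low-dose regimes.

A paired study reuses the baseline geometry and scales each lesion's true
SUV by its prescribed relative difference — a purely metabolic change.
Pre and post noise seeds derive independently from one study seed, so
paired generation is bit-reproducible.

The bundled 16-lesion cohort (`petresponse.cohort`) fixes the study
conditions for end-to-end validation: radii cycling 8/10/12/14 mm (all
above the evaluability bar), half the lesions at true SUV 10 (FDG-avid)
and half at 5, true RDs of −40% × 10, +20% × 5 and +50% × 1, 4-mm blur,
0.1 SUV noise.  These values are conditions, not tuning knobs.

What the phantoms do **not** emulate: CT anatomy, attenuation/scatter,
respiratory motion, heterogeneous lesion texture, reconstruction
artifacts, or uptake-time variation.  Passing the synthetic suite shows the
computational chain is correct under its stated model, not that it is
robust to everything real scans contain.

## Lesion delineation

The delineation emulates a commercial gradient-edge contouring tool whose
algorithm is proprietary; the surrogate is fully specified and
deterministic:

1. The operator supplies a seed voxel (approximate lesion center) and a
   drag voxel; the drag length sets the search scale.
2. 128 quasi-uniform rays (spherical Fibonacci lattice) are cast from the
   seed's voxel center and sampled at 1-mm steps out to twice the drag
   radius using cubic B-spline interpolation.
3. Per ray, the edge sits at the maximum-magnitude negative radial
   derivative (the falling flank), ties toward the smaller radius.  Rays
   with no falling flank inherit the median radius of the successful rays;
   if fewer than half succeed the tool reports "no edge detected" (a
   uniform image is the canonical case).
4. The star-convex region is voxelized by center inclusion (nearest-ray
   lookup) and smoothed twice.

Two numerical choices matter at 4-mm spacing.  *Cubic rather than
trilinear sampling*: a trilinear profile has piecewise-constant gradients,
so edges quantize to whole voxels and bias inward by up to half a voxel —
enough to halve the volume of a 10-mm lesion.  Cubic interpolation gives a
continuously varying gradient that localizes the edge within a voxel.
*Volume-preserving smoothing*: each pass Gaussian-filters the mask
indicator (σ = 1 voxel) and re-thresholds at
`max(0.25, min(0.5, v_keep))`, where `v_keep` is the value that preserves
the voxel count.  A plain 0.5 threshold acts as curvature flow and erodes
masks only a few voxels across (an 8-mm-radius lesion vanished entirely in
measurement); the cap lets smoothing round contours without eating volume,
while the 0.25 support floor still erodes isolated voxels and thin spikes
(an isolated voxel's smoothed indicator peaks near 0.06).  After
smoothing, only the 26-connected component containing the seed is kept.

Baseline contours are frozen and propagated to the follow-up and
PVC volumes by default (`propagate_baseline_masks`), isolating metabolic
change from segmentation variability; re-drawing on the follow-up is
available behind the flag.

Measured on noise-free blurred spheres, recovered volumes track the
analytic truth to a few percent in generic grid alignments; pathological
center-on-lattice alignments carry the inherent ±15–25% voxel-counting
fluctuation of a 2.5-voxel-radius ball.

## SUV quantification

* `SUV_max` / `SUV_mean`: maximum / arithmetic mean under the mask.
* `SUV_peak`: mean within a sphere of configurable volume (default 1 mL,
  radius 6.20 mm ≈ 1.24 cm diameter) centered at the hottest masked voxel.
  The sphere is voxelized by center inclusion, may extend beyond the mask,
  and is clipped to the image bounds.  Exact value ties (possible only on
  synthetic plateaus) break toward the voxel nearest the mask centroid,
  then the lowest linear index, so a perfectly uniform lesion peaks at its
  middle.  If the grid is too coarse for the sphere to span two voxels the
  peak is reported absent rather than fabricated.  An alternative placement
  that maximizes the sphere mean over all masked centers — used by some
  PERCIST implementations — is available via `maximize_sphere_mean`.
* `volume_ml`: voxel count × voxel volume.
* Filters: evaluable ⇔ volume ≥ 1.728 mL (inclusive: only targets
  *smaller* than the 3×3×3 block are excluded); FDG-avid ⇔ baseline
  **uncorrected** SUV_max ≥ 7.5 g/mL.  Avidity is decided once, on the raw
  baseline, and reused for the PVC arm, since the subset definition
  precedes any correction.
* `suv_from_activity` converts kBq/mL activity concentration to SUV via
  dose/body-mass normalisation for inputs not already in SUV units.

## Partial-volume correction

Image-domain damped Richardson–Lucy deconvolution applied to whole
volumes (not per-ROI), with the observed image as both data term and
initial estimate:

```
y_hat_k = C(x_k)                        C: PSF convolution, replicate padding
r_k     = 1 + w_k (y / y_hat_k − 1)     damped ratio
x_{k+1} = x_k · C^T(r_k)                C^T: mirrored-kernel convolution
w_k     = 1 − (1 − min(((y − y_hat_k)/T)², 1))²
```

Defaults: 5 iterations, damping threshold T = 0.1 SUV, separable Gaussian
PSF of FWHM 4 mm sampled on an 11-voxel-per-axis kernel and renormalised
to unit sum; subsampling factor fixed at 1 (any other value raises an
explicit unsupported-parameter error rather than silently approximating).
T = 0 recovers the classic undamped recursion.  The damping weight
attenuates updates where residuals are small relative to T, which limits
noise amplification; measured on noisy phantoms, the mean |output−input|
decreases monotonically in T (the per-voxel maximum does not, because
voxels with residuals ≫ T are undamped at any threshold).

Numerics: convolutions run as FFT convolution over an edge-padded array
(identical to direct convolution up to ~1e-15); replicate padding makes a
uniform image an exact fixed point and avoids torso-edge artifacts;
predicted values are floored at 1e-12 before the ratio; the output is
clipped at zero to remove FFT rounding dust.  The damping formula follows
the residual-attenuation family used in astronomy imaging; vendor
implementations may differ in the exact weight, which is why T is
configurable.

Behavioral checks (all in the test suite): delta-PSF identity, uniform
fixed point, agreement with a hand-rolled 1-D recursion to 1e-10,
non-increasing Kullback–Leibler data fidelity when undamped, monotone
maximum recovery on a blurred 8-mm-diameter sphere, and reduction of the
partial-volume bias of SUV_max for that lesion.  On lesions already large
relative to the PSF the first iteration can overshoot the true maximum and
then relax, so monotonicity is a small-lesion property.

## Response assessment

RD(%) = 100 (SUV_post − SUV_pre)/SUV_pre requires a positive baseline;
classification is response for RD ≤ +15, progression for RD ≥ +30,
indeterminate in the open interval — both boundaries inclusive toward
their named category.  Summaries count categories over one
(metric × subset × condition) block; only evaluable targets enter, the
FDG-avid subset additionally requires baseline raw SUV_max ≥ 7.5 g/mL, and
targets with an absent SUV_peak drop out of SUV_peak rows only.  Rates are
percentages rounded half-to-even at one decimal — the unique rounding
consistent with printed patterns like 13/16 → 81.2 and 1/16 → 6.2; empty
subsets report n = 0 with undefined rates rather than fabricated zeros.
Rounded triplets sum to 100.0 within ±0.1.

New-lesion detection — a clinical reading on real scans — is reduced to a
roster comparison utility (`compare_rosters`) and excluded from the
statistical summaries.

## Pipeline and reproducibility

`run_pipeline` chains simulate → segment → quantify → pvc → respond →
report into one output directory: volumes and masks as NIfTI-1, metrics
and per-target responses as CSV, cohort summaries as CSV + JSON, ground
truth and run manifest as JSON, plus the resolved configuration and a
stage-granular log (absent SUV_peak values are warned about, never
silently dropped).  Runs are bit-deterministic given the seed.

## Problem sizes

The validation suite uses 32³–48³ grids for unit-level checks and the full
96×96×64 cohort grid for end-to-end runs; the category-recovery check runs
100 independently seeded cohort replicates (the acceptance script reports
the same rate over 25), sizes chosen to keep a full run at desk scale on a
single CPU.

## Known limitations

* The delineation surrogate is *a* gradient-edge tool, not the vendor's;
  absolute contour agreement with commercial software is untested.
* Evaluability is a volume rule; a 28-voxel snake passes where a per-axis
  bounding-box rule might not.
* The RL damping semantics are one member of a family; vendor-exact
  behavior is unknown.
* SUV conversion supports body-mass normalisation only (no lean-body-mass
  or body-surface-area variants, no glucose or uptake-time correction).
* Phantom realism limits are listed under "Phantom model"; cohort-level
  conclusions transfer to real studies only insofar as the blur + additive
  noise model holds.
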