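# Methods

This note documents the models, algorithms and design choices behind
`hybridreg`: a coarse-to-fine rigid registration pipeline that aligns a
segmented 3-D CT bone volume with 2-D single-plane fluoroscopy frames, and
a knee-kinematics stage that reduces registered femur and tibia poses to
the six clinical joint parameters.

## Problem and geometry

Single-plane fluoroscopy gives a time series of 2-D projections of a
moving bone; a CT scan gives its 3-D shape once. Recovering the bone's
six rigid-body parameters per frame — translations (Tx, Ty, Tz) in mm and
rotations (Rx, Ry, Rz) in degrees — turns the 2-D video into 3-D
kinematics without implanted markers.

The camera is a point X-ray source with a flat detector:
source at the origin, optical axis +z, detector at
`source_to_detector_distance` (default 1000 mm). The bone's object frame
is centred on its voxel-grid centre, placed on the optical axis at
`source_to_object_distance` (default 600 mm), giving magnification
SDD/SOD ≈ 1.67 at the reference pose. A pose rotates the volume about its
grid centre with fixed axes in the order Rx, Ry, Rz and then translates.
Rotation order and centre are conventions — they are not observable from
images — chosen so that the in-plane parameters (Tx, Ty, Rz: motion
parallel to the detector) separate cleanly from the out-of-plane ones
(Tz, Rx, Ry). All units are mm and degrees everywhere, including configs
and logs.

## DRR projection

Digitally reconstructed radiographs are computed by fixed-step ray
marching: each detector pixel accumulates trilinear samples of the
attenuation volume along its source-to-pixel ray, multiplied by the step
(default: half the smallest voxel spacing, i.e. 0.5 mm for the default
phantom). Rays are clipped to the bounding box of nonzero voxels, so cost
scales with the projected bone area rather than the detector area.
Samples outside the volume contribute zero; a pixel whose ray misses the
bone is exactly zero. The projector is linear and homogeneous in the
volume by construction, which the tests exploit as invariants. An
orthographic mode (parallel rays) exists for analytic path-length tests
only. Exact-path integrators (Siddon/Joseph) and energy-dependent
attenuation are out of scope; step halving changes the default phantom's
DRR by well under 1% of dynamic range, which bounds the discretisation
error relevant here.

## Similarity measures

**EPD (edge position difference).** Canny edges of the DRR are scored
against a precomputed chamfer distance map of the fluoroscopy edges: the
value is the mean distance-to-nearest-edge over the transformed DRR edge
pixels. The mean (rather than the sum) keeps values comparable when
candidate transforms push different numbers of points outside the map;
points leaving the image are clamped to the border and penalised by the
out-of-bounds travel distance, which keeps the measure continuous and
removes the degenerate "slide everything off the image" minimum. The
distance map is the exact Euclidean distance transform; "chamfer" names
the role, and exactness permits a clean brute-force oracle. The classic
two-pass 3-4 weighted approximation is available behind a flag for
fidelity experiments. Canny thresholds are fractions of the smoothed
gradient-magnitude maximum (defaults 0.10/0.25, Gaussian sigma 1.5 px),
making the edge map invariant to affine intensity rescaling.

**SCV (sum of conditional variance).** Pixels are partitioned by the
moving (DRR) image's intensity bin (64 uniform bins over the image's own
range by default); the value is the pooled within-bin variance of the
reference (fluoroscopy) intensities, normalised by pixel count. SCV is
zero exactly when one image is a deterministic function of the other, so
it tolerates the unknown monotone nonlinear map between CT line integrals
and fluoroscopy grey levels. Conditioning on the DRR is the default
because the DRR is regenerated every iteration and the Gauss-Newton
residual is defined against it; the `expected_image` helper materialises
the per-bin conditional means, and the mean squared difference between
expected image and reference equals the SCV value by construction.

**Choice of intensity domain for SCV.** The pipeline can band-pass both
images with a Laplacian-of-Gaussian filter (sigma 2 px) before the SCV
stages (`scv_prefilter: "log"`), which is the appropriate choice for real
fluoroscopy where soft tissue, scatter and shading add structured
background that a pixelwise conditional model cannot absorb. The default
here is `"none"`: on frames whose relationship to the DRR is a pixelwise
monotone map plus noise — exactly what the synthetic generator produces —
the raw-intensity SCV has its minimum at the true pose, whereas LoG
filtering breaks the pixelwise functional relationship (LoG of a
nonlinearly remapped image is not a function of the LoG'd original) and
empirically displaces the depth (Tz) minimum by several millimetres on
these phantoms. Direct profile scans of both variants along Tz motivated
this default; the LoG path remains one config key away.

## The three-stage hybrid search

1. **Coarse in-plane, EPD.** Exhaustive grid over (Tx, Ty, Rz) — default
   ±20 mm at 1 mm and ±10° at 1° — with the out-of-plane parameters
   frozen. One DRR is cast at the initial pose; every candidate merely
   transforms the 2-D edge coordinates (rotation about the projected
   volume centre, then translation scaled to pixels at the current depth)
   and samples the distance map. Under perspective this is approximate —
   magnification varies with Tz — but Tz is fixed during the stage and
   the error is second order; this approximation is what makes ~35k
   candidates cost one projection. The exact re-projecting variant is
   available behind `exact_coarse` for validation.
2. **Fine in-plane, SCV.** Exhaustive search over ±2 mm / ±2° at 0.5
   steps around the coarse result; each candidate re-projects the volume.
3. **Final, (Rx, Ry) grid + Gauss-Newton.** For each cell of a ±10° / 5°
   out-of-plane grid (covering the study's ±5° perturbations with
   margin), a damped Gauss-Newton iteration refines (Tx, Ty, Rz, Tz):
   the residual is reference-minus-expected-image (so its mean square is
   the SCV), the Jacobian comes from central finite differences
   (0.5 mm / 0.5° steps), and the normal equations carry a
   Levenberg-Marquardt damping term (lambda times the diagonal of JᵀJ, so
   the weakly observable depth direction is not throttled) that grows
   tenfold on each rejected step — accepted-step SCV is therefore
   non-increasing by construction. Iteration stops when the mixed mm/deg
   step norm falls below 1e-3, after 30 iterations, or when damping is
   exhausted. The cell with the smallest final SCV wins. The 64-bin
   default matters here: with coarser binning the pooled binning error
   leaves a flat floor around the minimum along Tz and the iteration
   stalls a millimetre or more short; 64 bins sharpen the depth valley by
   an order of magnitude at no extra projection cost.

All grid searches are deterministic: ties break toward the candidate
nearest the stage's initial pose, then lexicographically. Search ranges,
steps, bin count and Gauss-Newton settings are config values, not
measured constants; none are claimed to match any particular clinical
system.

Efficiency is reported in DRR projections, the dominant unit of work: the
hybrid pipeline casts roughly 2–4 thousand DRRs per frame (one for the
coarse stage, 729 for the fine grid, the rest inside Gauss-Newton),
versus ~2.8 × 10⁸ for a hypothetical single-stage SCV full search over
the same six-parameter range at fine-stage resolution. Wall-clock speed
is hardware-bound and is not asserted anywhere; the counter ratio is the
portable claim.

## Synthetic phantoms and the 27-pose study

No imaging data ships with the package; the phantom module generates the
study inputs. A bone is a capped cylinder (shaft, radius 7 mm, cortical
shell 2.5 mm) along the object y axis with either a spherical condylar
end (femur-like, radius 10 mm) or a flat plateau disc (tibia-like),
voxelised from an analytic signed-distance function into a 64³ grid at
1 mm spacing: cortical attenuation 1.0 within the shell depth,
trabecular 0.3 with a mild seeded texture inside, exact zero background.
Fluoroscopy frames are DRRs pushed through inversion + gamma 0.6 (a
monotone, deliberately non-affine remap, so measures assuming a linear
intensity relationship genuinely fail), additive Gaussian noise (sigma
0.02 of unit range by default), and optionally pincushion distortion
(radial polynomial r(1 + k1·rho² + k2·rho⁴), rho normalised by the image
half-diagonal; correction resamples through the forward map, simulation
inverts it by Newton iteration). The deterministic signal is normalised
to [0, 1]; noise is left unclipped so its distribution is exactly the
stated Gaussian. Every generator output is a pure function of its spec
including seeds.

The evaluation design places the bone at all 27 combinations of
Rx, Ry ∈ {−5, 0, 5}° and Tz ∈ {−20, −10, 0} mm with in-plane parameters
zero, imaged on a 160×160 detector at 0.5 mm pitch. Each frame is
registered independently. Initial poses emulate the semi-automatic
first-frame protocol of fluoroscopy studies (manual placement then
automatic refinement): ground truth perturbed by seeded uniform offsets
of up to ±2 mm / ±2° in-plane and ±5 mm in depth, with Rx, Ry started at
zero and left to the out-of-plane grid. Under these conditions the study
recovers in-plane translations to a few microns-equivalent (MAE well
under 0.01 mm), Rz to ~0.02°, and Tz to ~0.6 mm MAE — depth is the
dominant error direction, as expected for single-plane geometry where Tz
only changes magnification by ~1.7% per 10 mm.

What the phantoms do **not** emulate: soft-tissue background, implants
and foreign objects, scatter, Poisson photon statistics, detector blur,
and anatomy-realistic bone shapes. Passing the study therefore
demonstrates the correctness and internal consistency of the pipeline —
not clinical-grade accuracy on real fluoroscopy, where the LoG prefilter
and careful Canny tuning would matter and errors would be larger.

## Knee kinematics

Registered femur and tibia poses are combined into the relative transform
(tibia in the femur frame) and decomposed in the floating-axis joint
coordinate system: e1 is the femoral medial-lateral axis,
e3 the tibial long axis, e2 = e3 × e1 the floating axis.
Flexion-extension is the rotation about e1, internal-external about e3,
abduction-adduction about e2; with the anatomical frames written as
orthonormal bases this is exactly the intrinsic x–y′–z″ Cardan sequence
of the matrix A_fᵀ R A_t. Translations are the components of the
femoral-origin-to-tibial-origin vector in the (generally non-orthogonal)
joint basis, obtained by solving the 3×3 system rather than by dot
products so that decompose/recompose is an exact round trip. All six
parameters are offset-referenced to the CT-capture configuration: the
identity relative pose reports zeros. Configurations where e1 and e3
become near-parallel (|sin| of the middle angle near 1) are rejected as
degenerate rather than silently extrapolated. For the synthetic phantoms
the anatomical axes come from the construction geometry (long axis = the
shaft axis, medial-lateral = the condylar x axis), so no landmarking
step exists. Rotations are reported in degrees and translations in mm.

## Numerical details and degenerate inputs

- Pose decomposition warns (recoverably) near |Ry| = 90° where the Euler
  split is not unique; the study never approaches this.
- `joint_histogram`/`scv` reject constant images (zero intensity range)
  rather than binning degenerately; inside Gauss-Newton such a candidate
  (bone fully out of view) is treated as a rejected step.
- The discrete LoG kernel's DC leak is subtracted so a constant image
  maps to exactly zero.
- The chamfer map of an empty edge image is an error, not an
  all-infinity map.
- Distance preservation, histogram conservation, 1-Lipschitz distance
  maps and SCV's monotonicity under bin refinement are enforced as
  property tests.

## Problem sizes used by the test suite

Unit tests run on a 32³ phantom at 2 mm spacing with a 96² detector and
reduced search grids; the acceptance tests and `scripts/acceptance.py`
run the full 64³ / 160² study (27 frames, ~10–12 minutes on one CPU) and
a 10-run Gauss-Newton recovery check. These sizes are the package's
standard desk-scale configuration; everything scales to larger volumes
through the same API.
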