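# Methods

This note documents the models, estimators and numerical choices behind
`regqa`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, and what the synthetic studies do
and do not demonstrate.

## Geometry and data model

All images are 3D scalar volumes on axis-aligned grids: 0-based voxel
indices ordered (x, y, z) with z the slice axis, and the voxel-center
convention `position = origin + index · spacing` (mm). Oblique direction
matrices are rejected at I/O rather than ignored, because a silently
dropped rotation corrupts every millimetre distance downstream. Masks
are boolean volumes, encoded 0/1 in unsigned 8-bit on disk. Contour
input is per-slice closed polygons in mm, rasterized by an even-odd
(ray-crossing) interior test at voxel centers; self-intersecting
polygons are rasterized under the same rule with a logged warning. The
reference NIfTI reader/writer is nibabel and the NRRD path goes through
SimpleITK; both round-trip data bit-exactly and geometry to 1e-6 mm.

## B-spline free-form deformations

A deformation is a tensor-product *cubic* B-spline over a regular
control-point lattice, storing a 3-vector mm displacement coefficient
per control point. The convention is forward everywhere: a material
point at `p` maps to `p + d(p)`. The lattice always covers the image
with at least one extra control point per side so every voxel has full
cubic support; evaluation refuses to extrapolate.

**Warping.** Dense images are resampled backward through the numerically
inverted forward map: per voxel, the fixed-point iteration
`x ← y − d(x)` (tolerance 0.01 mm, ≤ 20 sweeps — two orders below the
smallest tolerance any consumer asserts), then trilinear interpolation.
The fixed point converges precisely when the displacement-gradient
spectral norm is below 1, i.e. when the map does not fold; warping
raises if more than 0.1% of voxels fail to converge, advising a milder
deformation. The field of view extends half a voxel beyond the outer
voxel centers: source positions inside that border are edge-extended,
and only genuinely out-of-field positions receive the padding value.
This matters numerically — treating the outer centers as a hard edge
makes the sum-of-squared-differences objective discontinuous in the
transform parameters, which breaks any gradient-based consumer.

**Synthesis.** `random_transform` draws i.i.d. uniform coefficients in
[−a, +a] and zeroes every control point within two control spacings of a
volume face (or outside it); with a cubic basis this is the minimal rule
under which the displacement vanishes *exactly* on the faces, so probe
points never leave the frame and splatting conserves mass. An optional
Gaussian smoothing of the coefficient lattice (`smooth_sigma`, in
control-grid units) produces spatially coherent, longer-wavelength
fields. The graded families used in the validation studies smooth with
σ = 2 control points and then rescale amplitudes linearly to exact
full-volume RMS displacement targets (displacement is linear in the
coefficients, so the rescaling is exact). The smoothing is not
cosmetic: on a thoracic-scale frame, a *raw* i.i.d. field rescaled to a
full-volume RMS displacement of ~9 mm requires local displacement
gradients above 1 — a folding, non-invertible map that no longer
resembles an anatomical deformation and admits no recovery trajectory —
whereas the smoothed family reaches the same RMS with max |∇d| ≈ 0.66.

**Displacement error.** For a point sample {xᵢ},
`DE = sqrt(mean |εᵢ|²)` with εᵢ the residual displacement 3-vector, and
the axial DE the same RMS over the (x, y) components; "axial" is
interpreted as the in-plane component (the slice axis is excluded), a
deliberate reading documented here because thick-slice geometries make
the in-plane error the clinically scrutinized one. `true_de_dense`
evaluates the same RMS over every voxel of a frame via the separable
structure of the tensor product (one basis matrix per axis), streaming
x-slabs so the dense field is never materialized.

## The grid-probe estimator

The estimator measures displacements through an opaque image pipeline:
plant `n` unit-intensity probes at random voxel centers (uniform without
replacement, pairwise separation ≥ 3 in-plane voxels by default, which
is what keeps merging rare at the preferred 1000-probe density on
thoracic frames); deform by *forward splatting* — each probe's unit mass
deposited with trilinear weights on the 8 voxels around its mapped
subvoxel position, which preserves the mass centroid exactly; re-detect
probes as intensity-weighted centroids of 26-connected components above
5% of the maximum intensity; and match detections to known positions by
mutual nearest neighbor within a radius, keeping a pair only when the
second-nearest candidate on *both* sides is over 1.5× farther. Merged
or crossing probes therefore surface as ambiguity discards and a reduced
matched fraction — reported in every `DEReport`, flagged below 80% and
refused below 50% — rather than as silent bias.

Two instruments share this machinery:

* `approximate_de(before, after)` — the post-registration instrument: a
  perfectly recovered pipeline returns every probe to its planted
  position, so truth-to-detection offsets are small residuals and plain
  mutual-NN matching (default radius 15 mm) is valid. This is what the
  intra-modality study driver uses.
* `measure_transform_de(before, deformed, t_back)` — the deformation-
  magnitude instrument used in the estimator's self-validation: blobs
  are detected in the *deformed* image and their centroids carried back
  along a recovery trajectory (the numerically exact inverse in
  self-validation; a system's stored transform in an assessment).
  Carried-back positions sit within detection noise of the plant sites,
  so matching uses a tight 5 mm radius and εᵢ = (deformed detection −
  plant site). Matching raw deformed positions against original ones
  fails for a structural reason worth recording: once pointwise
  displacements exceed the inter-probe spacing (~21 mm at 1000 probes on
  a thoracic frame), nearest-neighbor correspondence locks onto wrong
  partners and the measured DE saturates near the spacing scale
  regardless of the truth.

**Self-validation design.** `accuracy_study` plants fresh grids per
transform, deforms, recovers correspondence along the exact inverse, and
tabulates measured against exact DE. The comparison reference is the
exact Eq. truth *at the planted probes*: the estimator is by
construction a sample approximation, and its measurement error
(detection centroids, merging, correspondence) is what the study
validates. The full-volume RMS is tabulated alongside
(`true_de_volume`), and the difference between the two is ordinary
sampling fluctuation of ~1000 probes against a spatially correlated
field — for the σ = 2 families the field's correlation length (~80 mm)
leaves only ≈ 100 effectively independent probes, so per-transform
sample-vs-volume deviations of 0.1–0.4 mm at large DE are expected and
carry no information about the estimator. The packaged experiment
(`run_accuracy_experiment`) uses twelve transforms spanning full-volume
DE ≈ 0.8–9.3 mm on the 512×512×43, 0.8×0.8×7.5 mm³ frame with
1000-probe grids; measured-vs-truth mean absolute differences are
≈ 0.02 mm (3D) and ≈ 0.005–0.01 mm (axial, restricted to transforms with
axial DE ≤ 7.08 mm) across seeds, and increasing the density to 3000 or
5000 probes strictly increases ambiguity discards at DE > 6 mm — the
crowding failure mode the matched-fraction bookkeeping exists to expose.

## Similarity measures

All histogram measures use a joint 2D histogram with 64 equal-width bins
per image by default over the robust 0.5–99.5 percentile range (values
outside are clipped into the edge bins so counts always sum to the
overlap size). NMI is the Studholme form (H(A)+H(B))/H(A,B) with
entropies in bits, equal to 2 for identical images under shared binning
and tending to 1 for independent ones; MI is H(A)+H(B)−H(A,B); the
symmetric correlation ratio averages the two directed η² =
Var(E[A|B-bin])/Var(A) with intensities represented by bin centers; CC
is Pearson correlation over the overlap and is omitted for
inter-modality pairs, where a linear intensity relation is not
meaningful. All voxels in the overlap grid participate — no background
masking — so similarity gains driven by structures away from the
clinical target (couches, body outline) deliberately show up in the
scores; absolute values depend on the binning choices and only
*orderings* are comparable across implementations. Setting rankings
sort per-setting means descending with stable lexicographic tie-breaks,
and ties are flagged in the result.

## Contour metrics

TC and DSC are computed by voxel counting on geometry-identical mask
pairs; both are undefined (an error) for two empty masks, and
DSC = 2·TC/(1+TC) holds to 1e-12 by construction. The mean surface
distance uses surface voxels (mask voxels with ≥ 1 false 6-neighbor,
volume faces counting as false), Euclidean voxel-center distances in mm,
and the symmetric average of the two directed means — sub-voxel surface
meshing was rejected as unverifiable against an exhaustive oracle, and
the symmetric mean avoids argument-order dependence. Masks that passed
through a trilinear resampler are re-binarized at 0.5.

## Digital phantom

The phantom is a water cylinder (default radius 100 mm, height 120 mm,
3 mm plastic wall) with a 10 mm plastic base slab and seven plastic
spheres of radii 5–15 mm; the slab's 12×12 grid of threaded mounting
holes at 8 mm pitch is carried as metadata (it fixes the translation
pitch of modification scenarios) but holes and mounting rods are not
rendered. Cylinder and sphere dimensions are configuration defaults
chosen to fit the acquisition matrices, not measured values. Rendering
is geometric: per-voxel material occupancy from 2×2×2 supersampling, a
material→intensity map per modality (CT: water 0 HU, plastic +120 HU,
air −1000 HU; T1 MRI: water 1000, plastic and air 0; PET: water activity
1, plastic and air 0), isotropic Gaussian blur at the system resolution
(0.7 / 0.8 / 6.5 mm FWHM for CT / MRI / PET) and additive Gaussian noise
seeded from the spec — the noise-free render is seed-independent. The
acquisition grids default to 512×512×62 @ 0.9×0.9×2.0 mm³ (CT),
512×512×21 @ 0.6×0.6×5.0 mm³ (MRI) and 144×144×30 @ 4 mm³ (PET).
Because plastic is a signal void on T1 MRI, the walled phantom's
half-maximum apparent radius is smaller on MRI than CT by roughly the
wall thickness — a deliberate, directionally testable emulation of the
modality-dependent boundary a registration system sees. What the
phantom does *not* emulate: beam hardening, MRI sequence contrast and
distortion, PET attenuation/scatter, or any anatomical variability;
conclusions from phantom scenarios speak to a system's treatment of
isolated local changes, not to clinical accuracy.

## Protocol harness

The black-box contract is two methods — `register(source, target,
setting) → handle` and `apply(handle, image) → image` — with the
guarantees that a handle is deterministic under re-application and may
be applied to any geometry-compatible image. Mock systems replay the
numerically exact inverse of the true transform attached to the
synthetic source's metadata, optionally composed with an injected
residual (a uniform offset or another B-spline) per "setting"; a zero
residual makes the mock a perfect registrar up to inversion tolerance,
which bounds every end-to-end zero check. Grid images are applied by
forward splatting of their nonzero voxels (preserving the subvoxel
centroid information the estimator depends on); dense images by backward
warping.

The reference registrar is deliberately minimal: gradient descent on the
B-spline coefficients of a forward transform under the
sum-of-squared-differences objective, evaluated exactly through the
warping path, with the gradient computed under the standard
small-deformation backward approximation. Steps are capped in mm,
carried adaptively across iterations (doubled on success, halved on
failure, five halvings before declaring divergence), so the accepted SSD
sequence is non-increasing by construction; a stall at numerical
precision counts as convergence. Its `seed` parameter exists for
interface uniformity — the optimizer is deterministic. Its role in the
protocol is to generate graded, data-driven families of plausible
transforms (every iteration snapshot is a milder version of the final
deformation), not to compete as a registration method; an optional
two-level smoothing pyramid helps with larger offsets. Rigid
pre-alignment is out of scope — study fixtures are generated
pre-aligned.

Study drivers: the intra-modality driver warps a baseline per true
transform, has the system register it back, pushes a deformed probe grid
through the stored transform and reports pre (exact, full-volume) versus
post (grid-probe) DE; the inter-modality driver applies the stored
transform to the binarized source mask, re-binarizes, and reports
TC/DSC/mean-surface-distance before and after; the relative driver
scores every (case, setting) pair with a similarity measure and ranks.
Mocks assume lossless image hand-off; a real system's export/import
resampling and quantization would add a floor to achievable post-DE that
these studies do not model.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed; there is no hidden
global RNG state, and derived sub-seeds stay below 2³¹. The validation
suite exercises the estimator at the full thoracic frame
(512×512×43, twelve transforms, ~15 s total on one CPU thanks to the
separable dense evaluation), and uses 64³-scale frames for the warping,
registrar and ranking studies — sizes chosen so the full suite runs in
about a minute while still covering every code path at clinically shaped
anisotropies. Mock-based Monte-Carlo checks (e.g. the 20-repeat setting
ranking) use small smooth synthetic images; passing them demonstrates
the machinery's correctness and ordering behavior, not the absolute
similarity values a clinical image pair would produce.

## Known limitations

* Axis-aligned geometry only; no DICOM/DICOM-RT ingestion.
* The forward-map inversion (and hence warping and recovery
  trajectories) requires non-folding fields; deformations with |∇d| ≥ 1
  are rejected rather than approximated.
* Grid-probe DE is a sample statistic: it cannot see deformations
  concentrated entirely between probes, and its estimates above the
  validated range (matched fraction < 80%) are flagged as unreliable.
* The similarity module's absolute values are binning-dependent; use
  them to rank, not to compare across tools.
* Mean surface distance is voxel-center based; for masks a few voxels
  across it overestimates sub-voxel agreement.
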