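# regqa — validation of black-box deformable image registration

Automatic deformable registration is used throughout image-guided
radiation therapy (dose accumulation, longitudinal response assessment,
multi-modality target delineation), yet the commercial systems that
perform it typically keep the deformation field inaccessible: the stored
transform can be re-applied to images, but never inspected. `regqa` is a
toolkit for quality-assuring such systems anyway. It is aimed at medical
physicists commissioning a registration product and at researchers who
need absolute, reproducible accuracy numbers from software they cannot
open.

The toolkit implements a four-component protocol:

1. **Digital phantom study** — a cylindrical water phantom with a plastic
   base slab and seven plastic spheres, rendered in CT, MRI and PET with
   modality-specific intensity maps, point-spread blur and noise. Paired
   scenarios (an 8 mm sphere translation, a sphere replacement) provide
   image pairs whose only difference is a known, local change.
2. **Relative validation** — post-registration similarity measures
   (normalized mutual information, mutual information, symmetric
   correlation ratio, correlation coefficient) computed from a joint
   intensity histogram, plus a harness that ranks the 36
   stiffness/speed/refinement setting permutations of a typical
   commercial system by per-case mean metric.
3. **Absolute intra-modality validation** — synthetic cubic B-spline
   free-form deformations of graded magnitude are applied to a baseline
   image; the system registers the warped image back, and the residual
   error is measured with a *grid probe*: a zero image with N sparse
   unit-intensity voxels whose exact positions are known. After the
   pipeline, probes are re-detected as intensity-weighted centroids of
   connected components and matched to truth, giving the displacement
   error

   DE = sqrt( (1/N) Σᵢ εᵢ² ),   εᵢ = |x̂ᵢ − xᵢ|,

   the RMS residual displacement over the probe sample (the axial DE is
   the same RMS over the in-plane (x, y) components). Because the probes
   travel *through* the image pipeline, DE is measurable even when the
   transform itself is not.
4. **Absolute inter-modality validation** — regions of interest on the
   two images are compared after registration by the Tannimoto
   coefficient TC = |A∩B|/|A∪B|, the Dice similarity coefficient
   DSC = 2|A∩B|/(|A|+|B|) (algebraically DSC = 2·TC/(1+TC)), and the
   symmetric mean surface distance in mm.

Every component runs end-to-end against *mock* systems (which replay a
known transform, optionally corrupted by an injected residual) and a
minimal reference B-spline SSD registrar, so the whole protocol is
executable and testable without any commercial software; a real system
is attached by implementing the two-method `BlackBoxSystem` contract
(`register`, `apply`).

## Worked example

Measure how accurately the grid probe reads off the displacement error
of three known deformations (target DE 1, 3 and 5 mm) on a
128×128×24 frame with 2×2×5 mm³ voxels, using 500 probes:

```python
import regqa

frame = regqa.FrameGeometry((128, 128, 24), (2.0, 2.0, 5.0))
family = regqa.graded_transform_family(frame, [1.0, 3.0, 5.0],
                                       control_spacing=16.0, seed=7)
table = regqa.accuracy_study(frame, family, n_points_options=(500,), seed=8)
print(table[["true_de", "measured_de", "true_axial", "measured_axial",
             "fraction_matched"]].round(3))
```

```
   true_de  measured_de  true_axial  measured_axial  fraction_matched
0    1.037        0.977       0.985           0.950             0.980
1    2.681        2.584       1.937           1.895             0.956
2    4.780        4.736       2.687           2.676             0.982
```

`true_de` is the exact RMS displacement of the planted probes under each
transform; `measured_de` is what the image-based pipeline recovers after
forward-splatting the probes, detecting them and re-establishing
correspondence — here within ~0.1 mm, with 95–98% of probes matched
(the remainder discarded as ambiguous rather than silently mismatched).

Contour metrics for two 20×20×10-voxel boxes offset by 2 mm on an
anisotropic grid:

```python
import numpy as np
a = np.zeros((40, 40, 20), bool); a[10:30, 10:30, 5:15] = True
b = np.roll(a, 2, axis=0)
ma = regqa.BinaryMask(a, (1.0, 1.0, 3.0))
mb = regqa.BinaryMask(b, (1.0, 1.0, 3.0))
m = regqa.contour_metrics(ma, mb)
print(f"TC={m.tc:.3f}  DSC={m.dsc:.3f}  MSD={m.mean_surface_distance_mm:.2f} mm")
```

```
TC=0.818  DSC=0.900  MSD=0.52 mm
```

## Command line

The `regqa` command exposes the protocol pieces: `regqa gridprobe`
(estimator accuracy study → CSV), `regqa similarity` and `regqa rank`
(similarity measures and setting ranking), `regqa contours` (overlap and
surface-distance metrics from masks or polygon contours),
`regqa phantom-study` (scenario image pairs, truth JSON and overlay
PNGs), and `regqa intra` / `regqa inter` (mock-driven study drivers).
Run any subcommand with `--help` for flags.

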