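# slotalign

Automated sample tracking and jitter correction for **Scanning Laser
Optical Tomography (SLOT)**.

SLOT images a rotating, optically cleared specimen with a weakly
focused scanned laser; a full rotation yields projection images that a
filtered back-projection turns into a tomogram. Image quality hinges on
two things that normally require a skilled operator: the sample must
rotate near the axis so the beam's focus length (twice the Rayleigh
length, `2·z_R = 2·n·λ/NA²`) can be kept short — a longer focus
directly costs lateral resolution (`0.61·λ/NA`, growing with the square
root of the covered diameter) — and residual frame-to-frame **jitter**
from the rotation stage must be removed before reconstruction, or the
tomogram shows doubled contours and streaks.

`slotalign` replaces the manual steps with two algorithms:

1. **Tracking** — an off-axis sample tumbles on a circle, so its
   lateral position in the frames follows `S(φ) = a·sin(φ + c) + d`
   and its distance to the focal plane the quadrature cosine
   `F(φ) = a·cos(φ + c) + F0 − a·cos(c)`. A low-angular-density fast
   pass is segmented frame by frame (CLAHE, unsharp mask, median,
   opening → Otsu → Canny contours → artifact filters → merged bounding
   box), the sinusoid is fitted by linear least squares, and per-angle
   field-of-view offsets and focus-stage positions are tabulated for
   the real acquisition.
2. **De-jittering** — each frame is segmented (optional rolling-ball
   background subtraction, Gaussian blur, GMM/Otsu/Canny binarization,
   opening, connected components), the object centroid is tracked, a
   sine is fitted to the centroid trace, and every frame is shifted by
   an integer pixel count onto the fitted curve (or onto the frame
   centre), iterating until the jitter error stalls. It needs no
   distinctive landmarks, so it works on homogeneously transparent
   samples.

A synthetic acquisition generator (tumbling absorbing sphere with an
optional dark inclusion, defocus blur, jitter, noise, cuvette/dust
artifacts, full ground truth) plus an in-package FBP and quality
metrics make the whole chain verifiable end to end.

## Worked example

```python
import slotalign as sa

# 1. plan the survey beam: focus length = 18 mm cuvette diameter
beam = sa.beam_from_coverage(18000.0, 0.532, 1.54)
print(f"survey beam: NA={beam.numerical_aperture:.4f}, "
      f"w0={beam.waist_radius:.2f} um, resolution={beam.lateral_resolution:.2f} um")

# 2. fast pass of a tumbling spheroid; fit its circular path
phantom = sa.PhantomSpec()
stack, truth = sa.simulate_acquisition(phantom, sa.AcquisitionSpec(beam=beam, seed=1))
trace = sa.track_stack(stack)
model = sa.fit_tumble(trace, stack.pixel_size)
print(f"tumble fit: a={model.amplitude:.2f} px ({model.amplitude_um:.0f} um), "
      f"c={model.phase:.3f} rad, d={model.axis_offset:.2f} px, "
      f"rmse={model.residual_rmse:.2f} px")
tight = sa.beam_for_sample(trace, stack.pixel_size, 0.532, 1.54)
print(f"tight beam after tracking: resolution={tight.lateral_resolution:.2f} um")

# 3. de-jitter a full acquisition and compare reconstructions
phantom = sa.PhantomSpec.with_inclusion()
acq = sa.AcquisitionSpec(n_frames=400, frame_shape=(160, 160), pixel_size=8.0,
                         tumble_amplitude=80.0, tumble_phase=0.3,
                         jitter_std=24.0, noise_std=0.01, seed=1)
stack, truth = sa.simulate_acquisition(phantom, acq)
corrected, shifts, report = sa.dejitter(stack, sa.SegmentationConfig())
print(f"dejitter: {report.iterations} iterations, "
      f"jitter error {report.jitter_error_per_iteration[0]:.2f} -> "
      f"{report.jitter_error_per_iteration[-1]:.2f} px, "
      f"final max residual {report.final_max_abs_residual:.2f} px")
gt = sa.attenuation_slice(phantom, 8.0, 160, vertical_offset_um=4.0,
                          tumble_amplitude=80.0, tumble_phase=0.3)
cmp = sa.compare_before_after(stack, corrected, 80, gt)
print(f"FBP row 80: correlation {cmp['correlation_raw']:.3f} -> "
      f"{cmp['correlation_corrected']:.3f}, "
      f"sharpness {cmp['sharpness_raw']:.2e} -> {cmp['sharpness_corrected']:.2e}")
```

Output:

```
survey beam: NA=0.0095, w0=31.46 um, resolution=34.01 um
tumble fit: a=53.25 px (1917 um), c=0.300 rad, d=109.52 px, rmse=0.16 px
tight beam after tracking: resolution=7.13 um
dejitter: 2 iterations, jitter error 2.72 -> 0.28 px, final max residual 0.54 px
FBP row 80: correlation 0.955 -> 0.980, sharpness 7.29e-05 -> 1.22e-04
```

Reading it: the wide survey beam resolves 34 µm but sees the whole
cuvette; the fast pass recovers the true tumble radius (1920 µm) to a
fraction of a pixel, after which the beam can be narrowed to the sample
itself (7.1 µm resolution — the payoff of tracking). The de-jitter loop
pulls a 3 px-RMS jitter down to the 0.5 px integer-shift floor, and the
reconstructed slice of the corrected stack is both closer to the true
phantom and sharper.

## Command line

Every stage is also a subcommand over TIFF stacks with JSON sidecars
(`{angles_deg, pixel_size_um, channel, roi, provenance}`):

```sh
slotalign simulate scenario.yaml --outdir data/
slotalign track data/stack.tif data/stack.json --model-out model.json
slotalign plan model.json --coverage 900 --n-angles 800 --out plan.csv
slotalign dejitter data/stack.tif data/stack.json --mode sine --vertical
slotalign reconstruct corrected.tif corrected.json --row 80
slotalign compare raw.tif raw.json corrected.tif corrected.json --row 80
slotalign run pipeline.yaml          # simulate -> track -> plan -> dejitter -> compare
```

`slotalign run` executes the whole offline workflow from one YAML
config with a single seed; identical config and seed give byte-identical
outputs.

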