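# Methods

`slotalign` implements the two automation algorithms a scanning laser
optical tomograph (SLOT) needs when the specimen cannot be mechanically
aligned to the rotation axis: fast-pass **sample tracking** with
per-angle field-of-view (FoV) and focus planning, and iterative
**jitter correction** of projection stacks, including for homogeneously
transparent samples. A synthetic acquisition generator with full ground
truth, a filtered back-projection (FBP) routine and before/after quality
metrics close the loop so that every stage is testable without an
instrument.

## Coordinate and intensity conventions

Frames are indexed `(row, col)`, origin top-left. The **column** axis is
the lateral/detector axis along which the tumbling sample moves and
sinogram rows are read; the **row** axis is vertical, parallel to the
rotation axis; the beam propagates perpendicular to the image plane.
Transmission intensities live in `(0, 1]` with `I0 = 1` for the
unattenuated background. All lengths are micrometres; angles at the API
surface are degrees, fitted phases radians.

## Beam planning

The usable focus length of a Gaussian beam is twice the Rayleigh length,
`2 z_R = 2 n λ / NA²`. Setting `2 z_R` equal to the diameter `d` that
must stay in focus gives `NA = sqrt(2 n λ / d)`,
`w0 = sqrt(z_R λ / (π n))`, and a lateral resolution we quote by the
Rayleigh criterion `0.61 λ / NA`. The resolution criterion is a design
choice — the instrument literature quotes a resolution of 34.01 µm for
the 18 mm survey configuration at λ = 532 nm, n = 1.54, and
`0.61 λ / NA` reproduces that figure to two decimals, which is why it
was adopted. Resolution grows with `sqrt(d)`: covering a 1920 µm-radius
tumble circle instead of a ~750 µm sample costs roughly a factor 2 of
resolution, which is the entire motivation for tracking.

A symbol note: the coverage diameter of the beam condition and the
axis offset of the tumble model are different quantities that share a
letter in the field's notation; here they are named `coverage_diameter`
and `axis_offset` and never meet in one formula.

## Tumble model

A sample embedded off-axis at radius `a` follows

    S(φ) = a·sin(φ + c) + d      (lateral position, px)
    F(φ) = a_um·cos(φ + c) + F0 − a_um·cos(c)   (focus stage, µm)

with phase `c`, axis column `d` and initial stage position `F0`. The
constant term of `F` is chosen so `F(0) = F0`: the stage starts where
the operator focused the sample at the initial angle, and the cosine
term then removes the rotation-caused axial excursion. (With a `−a·sin c`
constant this initial condition would not hold; the cosine form is used
deliberately and consistently.) The two trajectories are in exact
quadrature — the lateral sine leads the axial cosine by 90° of rotation
— which is property-tested.

Fitting uses the linear reparameterization
`S = A·sin φ + B·cos φ + d`, solved by least squares with
`a = hypot(A, B)`, `c = atan2(B, A)` normalized to `[−π, π)`. No
iterative optimizer and no initial guess are involved. At least five
valid detections spanning more than 180° are required; below that the
normal equations are ill-conditioned. When `a ≈ 0` the phase is
undefined and reported as 0.

## Detection chain (fast pass)

Per frame: optional inversion (the fluorescence channel is inverted so
both channels present a dark sample on a bright background), histogram
equalization, unsharp mask, median blur, grayscale opening, rescale to
[0, 1]. Equalization is the adaptive (CLAHE) variant: global
equalization stretches any smooth background gradient across the whole
intensity range, after which a global threshold splits the background
instead of the sample — CLAHE keeps the enhancement local and the
chain robust to the angle-dependent background brightness seen in real
acquisitions.

Binarization is Otsu's threshold with the **minority** intensity class
taken as the object, so dark-on-bright (transmission) and
bright-on-dark frames are handled identically. Canny edges of the
binary mask are closed and hole-filled, and the resulting contours are
filtered: area outside `[min_area, half the frame]`, more than 20 % of
the perimeter on the frame border (removes full-height cuvette-edge
bands), eccentricity above 0.98 (line-like artifacts). Surviving
contours are merged into one bounding box whose centre is the sample
coordinate — merging rather than picking the largest keeps fragmented
samples whole. A detection failure is a value (`valid=False` plus a
reason), never an exception. An optional ROI restricts detection to a
user-chosen rectangle — mirroring practice for small, highly
transparent samples — while coordinates are always reported in
full-frame pixels.

## Jitter correction

Each iteration: (optional) rolling-ball background subtraction,
Gaussian blur, binarization (Otsu default; 2-component GMM with the
threshold at the posterior crossover, or Canny-plus-fill, selectable),
morphological opening, 8-connected labelling, largest component above
the area floor (ties break to the top-left bounding box), centroid or
bounding-box centre. Components spanning the full frame height are
rejected: they are cuvette edges or the constant-fill borders that
earlier shifts introduce, never the sample. Transmission frames are
inverted first so the object is bright.

A sinusoid is fitted to the lateral centroid trace (same solver as the
tracking fit) and each frame is shifted by the integer pixel count that
puts its centroid on the curve; alternatively (`center_fit`) onto the
frame's centre column `W // 2`, which makes the sample rotate around
its own axis. Rounding is half-away-from-zero. Vertical correction,
off by default, fits a sinusoid **plus linear drift** to the row
centroids — a tilted rotation axis produces a per-revolution drift a
pure sine cannot capture — or uses the median row in `center_fit` mode.

The jitter error is the RMS residual of the centroids about the fit.
The loop stops when every shift of an iteration is within one pixel,
when the error improves by less than 0.01 px, or after
`max_iterations` (default 10); it aborts with a frame list if
segmentation fails on more than 20 % of frames. Shifts compose
additively across iterations. Because shifting is integer with constant
fill (the dark edge pixels visible at corrected sinogram borders) and
the injected displacement is continuous, the correction has a
principled residual floor of 0.5 px per direction; sub-pixel
interpolation is deliberately out of scope. Data reduction
(`crop_to_object`) removes rows above/below the object union and blanks
the background; columns are never touched, so lateral centroids are
unaffected.

What the correction cannot beat: the fitted sine is itself an estimate.
Its phase/offset error scales as `jitter_std·sqrt(k/n_frames)` (k ≈ 3
parameters), so on short stacks the corrected trajectory can deviate
from the true smooth path by over a pixel even though every centroid
sits on the fit. This is why validation sweeps use 400-frame stacks —
half the length of a real full acquisition (800 frames) — rather than
fast-pass-length stacks.

## Synthetic acquisitions

The generator renders a weakly absorbing sphere (default radius 400 µm,
µ = 1.5 × 10⁻³ /µm, i.e. ~30 % central transmission — a cleared
osteoblast spheroid) with an optional darker spherical inclusion
(radius 80 µm, µ = 6 × 10⁻³ /µm) standing in for the dead-cell
cavities that appear as dark spots in real spheroids. Omitting the
inclusion gives the featureless, homogeneously transparent sample that
defeats prominent-point sinogram methods. Transmission frames are
Beer–Lambert with analytic sphere-chord path lengths; fluorescence
frames are the line integral of fluorophore density (zero in the
inclusion), naturally inverted in contrast.

Per frame `k` at `φ_k = k·360/n`: lateral centre `a·sin(φ_k + c) + d`
plus i.i.d. Gaussian jitter (µm, sub-pixel, applied before
rasterization so integer correction has a genuine 0.5 px floor), axial
offset `a·cos(φ_k + c)`, vertical centre with optional per-revolution
drift and vertical jitter. Defocus blur is one Gaussian per frame with
`σ = w(z)/2` at the sample's mean axial offset (`w(z)/2` because the
1/e² beam radius is two intensity sigmas); per-pixel depth-dependent
blur would not change what the algorithms are tested on. Defaults
mirror the instrument's two scan modes: a 26-frame fast pass over 360°
at full FoV (36 µm/px) with tumble radius 1920 µm, and an 800-frame
500×477 px full acquisition (`AcquisitionSpec.full_acquisition()`).
Nuisance artifacts are opt-in flags: two dark full-height bands near
the frame borders (cuvette edges), three static high-contrast dust
specks, and a ±3 % lateral background gradient.

Not emulated: refraction through the embedding cylinder (the
angle-dependent brightness modulation of real data beyond a linear
gradient), photon statistics beyond additive Gaussian noise, scanner
timing, and the unexplained constant lateral offset observed in real
tracked acquisitions. Passing tests therefore demonstrate the
algorithms' correctness and convergence on geometrically faithful but
optically idealized data; they do not certify detection robustness
against strong refraction artifacts, for which the ROI preselection
exists.

## Reconstruction and metrics

Sinogram row `k` is row `r` of frame `k`. FBP converts intensities to
attenuation per angle with `I0` estimated as the median of the
outermost 5 % detector columns (configurable); pixels at or below a
small fill threshold are treated as vacated shift borders, i.e.
background. Projections are Ram-Lak filtered in the frequency domain
(zero-padded to the next power of two ≥ 2 W) and back-projected with
linear interpolation onto a `W × W` grid whose rotation centre is the
detector centre column `(W−1)/2`; the angular weight is `π / n_angles`.
Values outside the inscribed circle are untrustworthy (the classic
outer-ring artifact) and all metrics mask them out. The implementation
is deliberately in-package and is cross-checked in the tests against an
independent FBP (`skimage.transform.iradon`, which uses the opposite
angle sign convention).

Quality metrics: Tenengrad sharpness (mean squared Sobel gradient,
invariant to additive constants) and Pearson correlation with the
ground-truth attenuation slice, which the generator renders on the
reconstruction grid — including the off-axis sample position
`(a·sin c, a·cos c)` and the inclusion's angle-0 location. Sharpness
comparisons need adequate angular sampling: with very few angles the
streak artifacts of the *jittered* stack can out-gradient the true
edges.

## Validation problem sizes

Chosen to keep the full suite within a conventional CI budget while
preserving the statistics each check needs: fast-pass scenes use the
instrument defaults (26 frames, full FoV); de-jitter unit tests use
100–200-frame, 160×160 px stacks at 8 µm/px; the shift-recovery sweep
uses 400-frame stacks across ten seeds at jitter 1, 3 and 5 px, half
the runs with the featureless phantom; reconstruction comparisons use
200–400-frame stacks. The GMM binarization subsamples at most 20 000
intensities and runs at most 100 EM iterations with a fixed seed from
the configuration.

## Known limitations

* Integer shifting leaves up to 0.5 px per-direction residual by
  construction, plus the sine-estimation error described above.
* `center_fit` targets column `W // 2`; for even widths this sits half
  a pixel from the geometric centre `(W−1)/2` used by the FBP — a
  deliberate, documented integer convention.
* The rolling-ball implementation leaves a constant tangential gap
  under steep background slopes (harmless to thresholding) and edge
  effects within one ball radius of the border.
* Detection merges all surviving contours; a frame containing a second
  sample-like object inside the ROI will bias the bounding box — the
  ROI is the intended remedy.
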