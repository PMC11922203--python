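"""Iterative jitter correction for projection stacks.

Mechanical imperfections of the rotation stage displace the sample by a
random amount from frame to frame.  For homogeneously transparent
samples no prominent point exists to anchor a sinogram correction, so
this algorithm tracks the *whole* segmented object instead: per
iteration each frame is preprocessed (optional rolling-ball background
subtraction, Gaussian blur), binarized (GMM / Otsu / Canny+fill),
morphologically opened and labelled; the largest component's centroid
(or bounding-box centre) is the frame's sample coordinate.  A sinusoid
is fitted to the centroid trace and every frame is shifted horizontally
by the integer number of pixels that puts its centroid on the fitted
curve (alternatively onto the centre column of the frame).  The loop
repeats until the jitter error — the RMS residual of the centroids
about the fit — stops improving, all shifts are within one pixel, or an
iteration cap is reached.  Integer shifting leaves a principled sub-
pixel residual floor of 0.5 px; vacated pixels are filled with a
constant, which is the dark border visible at sinogram edges after
correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, restoration

from .stack import ProjectionStack
from .tracking import SineFit, fit_sine

__all__ = [
    "SegmentationConfig",
    "ShiftTable",
    "DejitterReport",
    "rolling_ball_background",
    "binarize",
    "segment_object",
    "object_centroid",
    "crop_to_object",
    "compute_shifts",
    "apply_shifts",
    "dejitter",
    "measure_centroids",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Detection/segmentation parameters of the de-jitter loop.

    Defaults follow the validated recipe for spheroid data: Gaussian
    filtering, Otsu thresholding and centroid tracking.  Rolling-ball
    background subtraction is available for data with smooth background
    gradients (it is optional in the processing chain and costly on
    large frames).  ``invert`` presents a bright object to the
    segmentation (transmission data has a dark sample on a bright
    background).  ``reject_full_height`` drops components spanning
    nearly the whole frame height (cuvette edges, fill borders).
    """

    background_method: str = "none"  # or "rolling_ball"
    ball_radius: float = 50.0
    blur_sigma: float = 2.0
    binarization: str = "otsu"  # "gmm", "otsu" or "canny_fill"
    opening_radius: int = 1
    min_object_area: int = 25
    centroid_mode: str = "centroid"  # or "bbox_center"
    invert: bool = True
    reject_full_height: bool = True
    gmm_seed: int = 0

    def __post_init__(self) -> None:
        if self.background_method not in ("rolling_ball", "none"):
            raise ValueError(f"unknown background_method {self.background_method!r}")
        if self.binarization not in ("gmm", "otsu", "canny_fill"):
            raise ValueError(f"unknown binarization {self.binarization!r}")
        if self.centroid_mode not in ("centroid", "bbox_center"):
            raise ValueError(f"unknown centroid_mode {self.centroid_mode!r}")
        if self.ball_radius < 0 or self.blur_sigma < 0:
            raise ValueError("radii and sigma must be non-negative")
        if self.min_object_area < 1:
            raise ValueError("min_object_area must be at least 1")


# --------------------------------------------------------------------------
# per-frame primitives


def rolling_ball_background(frame: np.ndarray, radius: float) -> np.ndarray:
    """Subtract a smooth rolling-ball background estimate; clip at zero.

    The background is what a ball of the given radius rolled under the
    intensity surface can touch; structures smaller than the ball
    survive the subtraction with their contrast, smooth gradients are
    removed.
    """
    frame = np.asarray(frame, dtype=float)
    if radius <= 0:
        raise ValueError("ball radius must be positive")
    if radius > max(frame.shape):
        raise ValueError(
            f"ball radius {radius} exceeds frame extent {max(frame.shape)}"
        )
    lo, hi = frame.min(), frame.max()
    if hi - lo < 1e-12:
        return np.zeros_like(frame)
    # the ball lives in (pixel, pixel, intensity) space; scale intensities to
    # the classic 8-bit-equivalent range so the radius means pixels
    work = (frame - lo) / (hi - lo) * 255.0
    background = restoration.rolling_ball(work, radius=radius)
    background = background / 255.0 * (hi - lo) + lo
    return np.clip(frame - background, 0.0, None)


def _gmm_threshold(values: np.ndarray, seed: int) -> float:
    """Posterior-crossover threshold of a 2-component 1D Gaussian mixture."""
    from sklearn.mixture import GaussianMixture

    sample = values.reshape(-1, 1)
    if len(sample) > 20000:
        rng = np.random.default_rng(seed)
        sample = sample[rng.choice(len(sample), 20000, replace=False)]
    gmm = GaussianMixture(
        n_components=2, max_iter=100, random_state=seed, n_init=1
    ).fit(sample)
    means = gmm.means_.ravel()
    lo, hi = float(means.min()), float(means.max())
    if hi - lo < 1e-9:
        return hi
    grid = np.linspace(lo, hi, 1001).reshape(-1, 1)
    post = gmm.predict_proba(grid)
    bright = int(np.argmax(means))
    crossing = np.nonzero(post[:, bright] >= 0.5)[0]
    if len(crossing) == 0:
        return (lo + hi) / 2.0
    return float(grid[crossing[0], 0])


def binarize(frame: np.ndarray, method: str = "otsu", gmm_seed: int = 0) -> np.ndarray:
    """Binarize a [0, 1] frame; foreground is the brighter class.

    ``gmm``: two-component Gaussian mixture on the intensity histogram,
    cut at the posterior crossover.  ``otsu``: Otsu's threshold.
    ``canny_fill``: Canny edges, closed and hole-filled.  A constant
    frame has no threshold: an empty mask is returned with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.max() - frame.min() < 1e-9:
        warnings.warn("constant frame: no binarization threshold exists", stacklevel=2)
        return np.zeros(frame.shape, dtype=bool)
    if method == "otsu":
        return frame > filters.threshold_otsu(frame)
    if method == "gmm":
        return frame > _gmm_threshold(frame.ravel(), gmm_seed)
    if method == "canny_fill":
        edges = feature.canny(frame, sigma=1.0)
        filled = ndi.binary_fill_holes(morphology.closing(edges, morphology.disk(1)))
        # snap the filled contour back onto the bright side of the edge
        return filled & (frame > filters.threshold_otsu(frame))
    raise ValueError(f"unknown binarization method {method!r}")


def segment_object(mask: np.ndarray, config: SegmentationConfig = SegmentationConfig()) -> Optional[np.ndarray]:
    """Largest connected component (8-connectivity) above the area floor.

    Returns the component as a boolean mask, or ``None`` when nothing
    survives.  Components spanning (almost) the full frame height are
    rejected when ``config.reject_full_height`` — those are cuvette
    edges or the constant-fill borders introduced by earlier shifts, not
    the sample.  Ties on area break toward the component whose bounding
    box starts at the smaller (row, col).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    rows = mask.shape[0]
    candidates = []
    for region in measure.regionprops(labels):
        if region.area < config.min_object_area:
            continue
        if config.reject_full_height and (region.bbox[2] - region.bbox[0]) >= rows - 1:
            continue
        candidates.append(region)
    if not candidates:
        return None
    candidates.sort(key=lambda r: (-r.area, r.bbox[0], r.bbox[1]))
    return labels == candidates[0].label


def object_centroid(region_mask: np.ndarray, mode: str = "centroid") -> Tuple[float, float]:
    """Sample coordinate ``(x_px, y_px)`` of a segmented region.

    ``centroid``: arithmetic mean of the member pixel coordinates (works
    for arbitrary, non-symmetric objects).  ``bbox_center``: midpoint of
    the bounding box (cheaper, symmetric objects only).
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    rr, cc = np.nonzero(region_mask)
    if len(rr) == 0:
        raise ValueError("empty region has no centroid")
    if mode == "centroid":
        return float(cc.mean()), float(rr.mean())
    if mode == "bbox_center":
        return (
            (float(cc.min()) + float(cc.max())) / 2.0,
            (float(rr.min()) + float(rr.max())) / 2.0,
        )
    raise ValueError(f"unknown centroid mode {mode!r}")


def crop_to_object(
    stack: ProjectionStack,
    row_bounds: Tuple[int, int],
    margin_px: int = 0,
    union_mask: Optional[np.ndarray] = None,
    fill_value: float = 0.0,
) -> ProjectionStack:
    """Data reduction: drop rows above/below the object, blank background.

    ``row_bounds`` is the (min_row, max_row) union of the per-frame
    object bounding boxes (inclusive).  Rows outside
    ``[min_row - margin, max_row + margin]`` are removed for the whole
    stack; columns are preserved so lateral centroids are unaffected.
    When a union foreground mask is given, pixels outside it are set to
    ``fill_value``.
    """
    rows = stack.frame_shape[0]
    lo = max(int(row_bounds[0]) - margin_px, 0)
    hi = min(int(row_bounds[1]) + margin_px, rows - 1)
    if lo > hi:
        raise ValueError(f"crop rows [{lo}, {hi}] are empty")
    frames = stack.frames[:, lo : hi + 1, :].copy()
    if union_mask is not None:
        sub = np.asarray(union_mask, dtype=bool)[lo : hi + 1, :]
        frames[:, ~sub] = fill_value
    out = stack.copy(frames=frames)
    out.meta["crop_rows"] = (lo, hi)
    return out


# --------------------------------------------------------------------------
# shifts


@dataclass
class ShiftTable:
    """Integer per-frame corrections; +dx moves content toward higher columns."""

    dx: np.ndarray
    dy: np.ndarray
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx)
        self.dy = np.asarray(self.dy)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 1:
            raise ValueError("dx and dy must be matching 1D arrays")
        for arr in (self.dx, self.dy):
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError("shift entries must be integers")

    def __len__(self) -> int:
        return len(self.dx)

    def __add__(self, other: "ShiftTable") -> "ShiftTable":
        return ShiftTable(self.dx + other.dx, self.dy + other.dy, self.fill_value)


def _round_half_away(values: np.ndarray) -> np.ndarray:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4)."""
    v = np.asarray(values, dtype=float)
    return np.trunc(v + np.copysign(0.5, v)).astype(int)


def compute_shifts(
    centroids_xy: np.ndarray,
    angles_deg: np.ndarray,
    mode: str = "sine_fit",
    vertical: bool = False,
    frame_shape: Optional[Tuple[int, int]] = None,
    fill_value: float = 0.0,
) -> Tuple[ShiftTable, SineFit]:
    """Integer shifts that move each centroid onto the target trajectory.

    ``sine_fit``: fit ``x(phi) = a sin(phi + c) + d`` to the lateral
    centroids and shift toward the fitted curve — the sample keeps its
    circular path, only the irregular part is removed.  ``center_fit``:
    shift toward the frame's centre column ``W // 2`` so the sample
    rotates around its own axis (requires ``frame_shape``).  Rows with
    NaN centroids (failed segmentation) get zero shift and are excluded
    from the fit.  With ``vertical``, row shifts toward a
    sinusoid-plus-linear-drift fit (``sine_fit``) or the median row
    (``center_fit``) are added.  Rounding is half-away-from-zero.
    """
    xy = np.asarray(centroids_xy, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) != len(angles):
        raise ValueError("centroids must be (n, 2) matching the angle list")
    ok = np.isfinite(xy).all(axis=1)
    if ok.sum() < 5:
        raise ValueError(f"need at least 5 centroids to fit, got {int(ok.sum())}")

    n = len(xy)
    dx = np.zeros(n, dtype=int)
    dy = np.zeros(n, dtype=int)
    if mode == "sine_fit":
        fit = fit_sine(angles[ok], xy[ok, 0])
        dx[ok] = _round_half_away(fit.predict(angles[ok]) - xy[ok, 0])
    elif mode == "center_fit":
        if frame_shape is None:
            raise ValueError("center_fit needs frame_shape")
        target = frame_shape[1] // 2
        dx[ok] = _round_half_away(target - xy[ok, 0])
        fit = SineFit(0.0, 0.0, float(target), 0.0,
                      float(np.sqrt(np.mean((xy[ok, 0] - target) ** 2))))
    else:
        raise ValueError(f"unknown shift mode {mode!r}")

    if vertical:
        if mode == "sine_fit":
            vfit = fit_sine(angles[ok], xy[ok, 1], drift=True)
            dy[ok] = _round_half_away(vfit.predict(angles[ok]) - xy[ok, 1])
        else:
            med = float(np.median(xy[ok, 1]))
            dy[ok] = _round_half_away(med - xy[ok, 1])
    return ShiftTable(dx, dy, fill_value), fit


def apply_shifts(stack: ProjectionStack, shifts: ShiftTable) -> ProjectionStack:
    """Translate each frame by integer (dx, dy); no wrap-around.

    Vacated pixels take ``shifts.fill_value`` (default 0 — the dark edge
    pixels visible in corrected sinograms); content shifted out of the
    frame is discarded.
    """
    if len(shifts) != len(stack):
        raise ValueError(
            f"{len(shifts)} shifts for {len(stack)} frames"
        )
    rows, cols = stack.frame_shape
    if np.any(np.abs(shifts.dx) >= cols) or np.any(np.abs(shifts.dy) >= rows):
        raise ValueError("shift magnitude meets or exceeds the frame extent")
    out = np.full_like(stack.frames, shifts.fill_value)
    for k, (sx, sy) in enumerate(zip(shifts.dx, shifts.dy)):
        src = stack.frames[k]
        r0d, r1d = max(sy, 0), rows + min(sy, 0)
        c0d, c1d = max(sx, 0), cols + min(sx, 0)
        r0s, r1s = max(-sy, 0), rows + min(-sy, 0)
        c0s, c1s = max(-sx, 0), cols + min(-sx, 0)
        out[k, r0d:r1d, c0d:c1d] = src[r0s:r1s, c0s:c1s]
    return stack.copy(frames=out)


# --------------------------------------------------------------------------
# the loop


@dataclass
class DejitterReport:
    """Per-iteration diagnostics of the correction loop."""

    iterations: int
    jitter_error_per_iteration: list  # RMS centroid residual about the fit, px
    final_max_abs_residual: float  # px, after all corrections
    mode: str
    vertical_applied: bool
    sine_fits: list = field(default_factory=list)  # SineFit per iteration

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("at least one iteration must have run")
        if any(e < 0 for e in self.jitter_error_per_iteration):
            raise ValueError("jitter errors must be non-negative")


def _measure_frame(frame: np.ndarray, config: SegmentationConfig) -> Tuple[float, float]:
    work = np.asarray(frame, dtype=float)
    if config.invert:
        work = work.max() - work
    if config.background_method == "rolling_ball":
        work = rolling_ball_background(work, config.ball_radius)
    if config.blur_sigma > 0:
        work = ndi.gaussian_filter(work, config.blur_sigma)
    mask = binarize(work, config.binarization, config.gmm_seed)
    if config.opening_radius > 0:
        mask = morphology.opening(mask, morphology.disk(config.opening_radius))
    region = segment_object(mask, config)
    if region is None:
        return math.nan, math.nan
    return object_centroid(region, config.centroid_mode)


def measure_centroids(stack: ProjectionStack, config: SegmentationConfig) -> np.ndarray:
    """Per-frame sample coordinates ``(x_px, y_px)``; NaN where segmentation fails."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-frame warnings count as failures
        return np.array([_measure_frame(f, config) for f in stack.frames])


def dejitter(
    stack: ProjectionStack,
    config: SegmentationConfig = SegmentationConfig(),
    mode: str = "sine_fit",
    vertical: bool = False,
    max_iterations: int = 10,
    fill_value: float = 0.0,
    min_improvement: float = 1e-2,
) -> Tuple[ProjectionStack, ShiftTable, DejitterReport]:
    """Iteratively shift frames until the centroid trace follows the fit.

    Stops when every shift of the last iteration is within one pixel,
    when the jitter error improves by less than ``min_improvement`` px,
    or after ``max_iterations``.  Aborts when segmentation fails on more
    than 20 % of frames.  Returns the corrected stack, the cumulative
    shift table and a per-iteration report.
    """
    n = len(stack)
    cumulative = ShiftTable(np.zeros(n, dtype=int), np.zeros(n, dtype=int), fill_value)
    current = stack
    errors: list = []
    fits: list = []
    for iteration in range(1, max_iterations + 1):
        centroids = measure_centroids(current, config)
        bad = np.nonzero(~np.isfinite(centroids).all(axis=1))[0]
        if len(bad) > 0.2 * n:
            raise RuntimeError(
                f"segmentation failed on {len(bad)}/{n} frames: "
                f"{bad.tolist()[:20]}"
            )
        shifts, fit = compute_shifts(
            centroids,
            stack.angles_deg,
            mode=mode,
            vertical=vertical,
            frame_shape=stack.frame_shape,
            fill_value=fill_value,
        )
        errors.append(_jitter_error(centroids, stack.angles_deg, fit, vertical))
        fits.append(fit)
        current = apply_shifts(current, shifts)
        cumulative = cumulative + shifts
        max_shift = max(
            int(np.abs(shifts.dx).max()), int(np.abs(shifts.dy).max())
        )
        if max_shift <= 1:
            break
        if len(errors) >= 2 and errors[-2] - errors[-1] < min_improvement:
            break

    # final residual about the fit, measured on the corrected stack
    centroids = measure_centroids(current, config)
    ok = np.isfinite(centroids).all(axis=1)
    _, fit = compute_shifts(
        centroids, stack.angles_deg, mode=mode, vertical=vertical,
        frame_shape=stack.frame_shape, fill_value=fill_value,
    )
    resid_x = np.abs(fit.predict(stack.angles_deg[ok]) - centroids[ok, 0])
    final_resid = float(resid_x.max()) if len(resid_x) else math.nan
    if vertical:
        vfit = fit_sine(stack.angles_deg[ok], centroids[ok, 1], drift=True)
        final_resid = max(
            final_resid,
            float(np.abs(vfit.predict(stack.angles_deg[ok]) - centroids[ok, 1]).max()),
        )
    report = DejitterReport(
        iterations=len(errors),
        jitter_error_per_iteration=errors,
        final_max_abs_residual=final_resid,
        mode=mode,
        vertical_applied=vertical,
        sine_fits=fits,
    )
    return current, cumulative, report


def _jitter_error(centroids: np.ndarray, angles_deg: np.ndarray, fit: SineFit,
                  vertical: bool) -> float:
    ok = np.isfinite(centroids).all(axis=1)
    resid = fit.predict(np.asarray(angles_deg)[ok]) - centroids[ok, 0]
    err2 = np.mean(resid**2)
    if vertical:
        vfit = fit_sine(np.asarray(angles_deg)[ok], centroids[ok, 1], drift=True)
        err2 += np.mean((vfit.predict(np.asarray(angles_deg)[ok]) - centroids[ok, 1]) ** 2)
    return float(np.sqrt(err2))
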