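"""Fast-pass sample tracking: detection, tumble fit, acquisition planning.

An off-axis-embedded sample tumbles on a circle around the rotation
axis.  In the projection frames its lateral (column) position follows

    S(phi) = a * sin(phi + c) + d        [pixels]

and its distance from the focal plane follows the quadrature cosine

    F(phi) = a_um * cos(phi + c) + F0 - a_um * cos(c)   [µm]

with ``F(0) = F0``, the focus stage's initial position.  This module
detects the sample in each fast-pass frame, fits the sinusoid by linear
least squares on the sin/cos basis, and tabulates per-angle field-of-view
offsets and focus-stage positions for the subsequent full acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, feature, filters, measure, morphology

from .beam_optics import BeamGeometry, beam_from_coverage
from .stack import ProjectionStack

__all__ = [
    "PreprocessConfig",
    "DetectionConfig",
    "Detection",
    "DetectionTrace",
    "TumbleModel",
    "AcquisitionPlan",
    "SineFit",
    "fit_sine",
    "preprocess_fastpass",
    "detect_sample",
    "track_stack",
    "fit_tumble",
    "fov_offset",
    "focus_position",
    "plan_acquisition",
    "beam_for_sample",
]


# --------------------------------------------------------------------------
# preprocessing


@dataclass(frozen=True)
class PreprocessConfig:
    """Fast-pass preprocessing chain parameters.

    ``invert`` flips the contrast first (used for the fluorescence
    channel so both channels present a dark sample on a bright
    background); then histogram equalization (adaptive/CLAHE, which
    keeps smooth background gradients from being stretched across the
    whole intensity range), unsharp mask, median blur and grayscale
    morphological opening are applied in that order and the result is
    rescaled to [0, 1].
    """

    invert: bool = False
    equalize: bool = True
    clahe_clip: float = 0.02
    unsharp_radius: float = 2.0
    unsharp_amount: float = 1.0
    median_size: int = 3
    opening_radius: int = 1

    def __post_init__(self) -> None:
        if self.median_size % 2 == 0:
            raise ValueError(f"median kernel must be odd, got {self.median_size}")
        if self.median_size < 1 or self.opening_radius < 0:
            raise ValueError("median_size >= 1 and opening_radius >= 0 required")


def preprocess_fastpass(frame: np.ndarray, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Apply the fast-pass preprocessing chain; output in [0, 1], shape kept."""
    out = np.asarray(frame, dtype=float)
    if out.ndim != 2:
        raise ValueError("frame must be 2D")
    lo, hi = out.min(), out.max()
    if hi - lo < 1e-12:  # constant frame: nothing to enhance
        return np.clip(out, 0.0, 1.0)
    out = (out - lo) / (hi - lo)
    if config.invert:
        out = 1.0 - out
    if config.equalize:
        out = exposure.equalize_adapthist(out, clip_limit=config.clahe_clip)
    if config.unsharp_amount > 0:
        out = filters.unsharp_mask(
            out, radius=config.unsharp_radius, amount=config.unsharp_amount
        )
    if config.median_size > 1:
        out = ndi.median_filter(out, size=config.median_size)
    if config.opening_radius > 0:
        out = morphology.opening(out, morphology.disk(config.opening_radius))
    lo, hi = out.min(), out.max()
    if hi - lo > 1e-12:
        out = (out - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------------------
# detection


@dataclass(frozen=True)
class DetectionConfig:
    """Contour-filter parameters for sample detection.

    Contours are rejected when their area falls outside
    ``[min_area, max_area_frac * frame_area]``, when more than
    ``border_frac`` of their perimeter lies on the frame border (removes
    cuvette-edge bands), or when their eccentricity exceeds
    ``max_eccentricity`` (removes line-like artifacts).  ``roi``
    restricts detection to a ``(row0, col0, row1, col1)`` rectangle; the
    reported coordinates stay in full-frame pixels.
    """

    min_area: float = 80.0
    max_area_frac: float = 0.5
    border_frac: float = 0.2
    max_eccentricity: float = 0.98
    canny_sigma: float = 1.0
    roi: Optional[Tuple[int, int, int, int]] = None


@dataclass
class Detection:
    bbox: Optional[Tuple[int, int, int, int]]  # (x0, y0, x1, y1), half-open px
    center: Optional[Tuple[float, float]]  # (x_px, y_px)
    valid: bool
    reason: str = ""


def detect_sample(frame: np.ndarray, config: DetectionConfig = DetectionConfig()) -> Detection:
    """Locate the sample in a preprocessed frame.

    Otsu binarization (the minority intensity class is taken as the
    object, so the chain works for dark-on-bright and bright-on-dark
    frames alike), Canny edge detection, closing of the edge contours
    and hole filling, then the rejection filters of ``DetectionConfig``.
    Bounding boxes of all surviving contours are merged; the box centre
    is the sample coordinate.  An empty result is a value
    (``valid=False`` with a reason), never an exception.
    """
    full = np.asarray(frame, dtype=float)
    r_off = c_off = 0
    if config.roi is not None:
        r0, c0, r1, c1 = config.roi
        full_shape = full.shape
        if not (0 <= r0 < r1 <= full_shape[0] and 0 <= c0 < c1 <= full_shape[1]):
            raise ValueError(f"roi {config.roi} outside frame {full_shape}")
        full = full[r0:r1, c0:c1]
        r_off, c_off = r0, c0
    if full.max() - full.min() < 1e-12:
        return Detection(None, None, False, "constant frame")

    threshold = filters.threshold_otsu(full)
    above = full > threshold
    binary = ~above if above.mean() > 0.5 else above  # object = minority class
    edges = feature.canny(binary.astype(float), sigma=config.canny_sigma)
    closed = morphology.closing(edges, morphology.disk(1))
    regions_mask = ndi.binary_fill_holes(closed) | binary
    labels = measure.label(regions_mask, connectivity=2)
    if labels.max() == 0:
        return Detection(None, None, False, "no contours after filtering")

    rows, cols = full.shape
    max_area = config.max_area_frac * rows * cols
    survivors = []
    for region in measure.regionprops(labels):
        if not (config.min_area <= region.area <= max_area):
            continue
        if region.eccentricity > config.max_eccentricity:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        on_border = np.count_nonzero(
            (rr == 0) | (rr == rows - 1) | (cc == 0) | (cc == cols - 1)
        )
        perimeter = max(region.perimeter, 1.0)
        if on_border / perimeter > config.border_frac:
            continue
        survivors.append(region)
    if not survivors:
        return Detection(None, None, False, "no contours after filtering")

    r0 = min(reg.bbox[0] for reg in survivors) + r_off
    c0 = min(reg.bbox[1] for reg in survivors) + c_off
    r1 = max(reg.bbox[2] for reg in survivors) + r_off
    c1 = max(reg.bbox[3] for reg in survivors) + c_off
    center = ((c0 + c1 - 1) / 2.0, (r0 + r1 - 1) / 2.0)
    return Detection((c0, r0, c1, r1), center, True)


@dataclass
class DetectionTrace:
    """Per-frame detections of a fast pass."""

    angles_deg: np.ndarray
    detections: list  # of Detection

    def __post_init__(self) -> None:
        if len(self.angles_deg) != len(self.detections):
            raise ValueError("one detection per angle required")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.array([det.valid for det in self.detections])

    def valid_centers(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(angles, x_px, y_px) of the valid detections."""
        mask = self.valid_mask
        xs = np.array([d.center[0] for d, m in zip(self.detections, mask) if m])
        ys = np.array([d.center[1] for d, m in zip(self.detections, mask) if m])
        return np.asarray(self.angles_deg)[mask], xs, ys

    def max_bbox_extent_px(self) -> float:
        """Largest bounding-box side among valid frames (sample diameter, px)."""
        extents = [
            max(d.bbox[2] - d.bbox[0], d.bbox[3] - d.bbox[1])
            for d in self.detections
            if d.valid
        ]
        if not extents:
            raise ValueError("no valid detections")
        return float(max(extents))


def track_stack(
    stack: ProjectionStack,
    preprocess: Optional[PreprocessConfig] = None,
    detection: DetectionConfig = DetectionConfig(),
) -> DetectionTrace:
    """Run preprocessing + detection over every frame of a stack."""
    if preprocess is None:
        preprocess = PreprocessConfig(invert=(stack.channel == "fluorescence"))
    dets = [
        detect_sample(preprocess_fastpass(frame, preprocess), detection)
        for frame in stack.frames
    ]
    return DetectionTrace(angles_deg=stack.angles_deg, detections=dets)


# --------------------------------------------------------------------------
# sine fitting


@dataclass
class SineFit:
    """``v(phi) = amplitude*sin(phi + phase) + offset [+ slope*phi]``."""

    amplitude: float
    phase: float
    offset: float
    slope: float
    rmse: float

    def predict(self, angles_deg) -> np.ndarray:
        phi = np.deg2rad(np.asarray(angles_deg, dtype=float))
        return (
            self.amplitude * np.sin(phi + self.phase)
            + self.offset
            + self.slope * phi
        )


def fit_sine(angles_deg, values, drift: bool = False) -> SineFit:
    """Least-squares sinusoid fit via the linear sin/cos reparameterization.

    ``v = A sin(phi) + B cos(phi) + d [+ e*phi]`` is solved by normal
    equations (no iterative optimizer, no initial guess), then
    ``a = hypot(A, B)``, ``c = atan2(B, A)`` normalized to [-pi, pi).
    """
    phi = np.deg2rad(np.asarray(angles_deg, dtype=float))
    v = np.asarray(values, dtype=float)
    if phi.shape != v.shape or phi.ndim != 1:
        raise ValueError("angles and values must be matching 1D arrays")
    cols = [np.sin(phi), np.cos(phi), np.ones_like(phi)]
    if drift:
        cols.append(phi)
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    a = float(np.hypot(coef[0], coef[1]))
    c = float(math.atan2(coef[1], coef[0])) if a > 1e-9 else 0.0
    c = (c + math.pi) % (2.0 * math.pi) - math.pi
    slope = float(coef[3]) if drift else 0.0
    resid = v - design @ coef
    rmse = float(np.sqrt(np.mean(resid**2)))
    return SineFit(amplitude=a, phase=c, offset=float(coef[2]), slope=slope, rmse=rmse)


# --------------------------------------------------------------------------
# tumble model and planning


@dataclass
class TumbleModel:
    """Fitted tumble sinusoid driving FoV and focus trajectories."""

    amplitude: float  # a, px
    phase: float  # c, radians in [-pi, pi)
    axis_offset: float  # d, px
    amplitude_um: float  # a * pixel_size
    stage_position_initial: float = 0.0  # µm
    residual_rmse: float = 0.0  # px

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.residual_rmse < 0:
            raise ValueError("amplitude and residual_rmse must be non-negative")
        if not (-math.pi <= self.phase < math.pi):
            raise ValueError("phase must be normalized to [-pi, pi)")


def fit_tumble(
    trace: DetectionTrace,
    pixel_size: float,
    stage_position_initial: float = 0.0,
) -> TumbleModel:
    """Fit ``S(phi) = a sin(phi + c) + d`` to the valid detections.

    Requires at least 5 valid detections spanning more than 180° of
    rotation (the sin/cos system is ill-conditioned below that).
    """
    angles, xs, _ = trace.valid_centers()
    if len(xs) < 5:
        raise ValueError(
            f"need at least 5 valid detections to fit, got {len(xs)}"
        )
    span = float(np.ptp(angles))
    if span <= 180.0:
        raise ValueError(
            f"valid detections span only {span:.1f} deg; > 180 deg required"
        )
    fit = fit_sine(angles, xs)
    return TumbleModel(
        amplitude=fit.amplitude,
        phase=fit.phase,
        axis_offset=fit.offset,
        amplitude_um=fit.amplitude * pixel_size,
        stage_position_initial=stage_position_initial,
        residual_rmse=fit.rmse,
    )


def fov_offset(model: TumbleModel, angle_deg: float):
    """Lateral FoV offset ``a*sin(phi + c) + d`` in pixels."""
    phi = np.deg2rad(np.asarray(angle_deg, dtype=float))
    out = model.amplitude * np.sin(phi + model.phase) + model.axis_offset
    return float(out) if np.ndim(angle_deg) == 0 else out


def focus_position(model: TumbleModel, angle_deg: float):
    """Focus-stage position in µm.

    ``F(phi) = a_um*cos(phi + c) + F0 - a_um*cos(c)``; the constant term
    removes the rotation-caused part so that ``F(0) = F0``, the stage
    position at the start of the acquisition.
    """
    phi = np.deg2rad(np.asarray(angle_deg, dtype=float))
    out = (
        model.amplitude_um * np.cos(phi + model.phase)
        + model.stage_position_initial
        - model.amplitude_um * math.cos(model.phase)
    )
    return float(out) if np.ndim(angle_deg) == 0 else out


@dataclass
class AcquisitionPlan:
    """Per-angle FoV offsets and focus positions for the full acquisition."""

    angles_deg: np.ndarray
    fov_offsets_px: np.ndarray
    focus_positions_um: np.ndarray
    fov_size: Tuple[int, int]
    beam: BeamGeometry

    def __post_init__(self) -> None:
        n = len(self.angles_deg)
        if len(self.fov_offsets_px) != n or len(self.focus_positions_um) != n:
            raise ValueError("plan columns must have one entry per angle")
        if not np.all(np.isfinite(self.focus_positions_um)):
            raise ValueError("focus positions must be finite")

    def to_rows(self) -> list:
        return [
            {
                "angle_deg": float(a),
                "fov_offset_px": float(o),
                "focus_um": float(f),
            }
            for a, o, f in zip(
                self.angles_deg, self.fov_offsets_px, self.focus_positions_um
            )
        ]


def beam_for_sample(
    trace: DetectionTrace,
    pixel_size: float,
    wavelength: float,
    refractive_index: float,
) -> BeamGeometry:
    """Plan the tight beam whose focus length matches the detected sample.

    Coverage diameter = largest bounding-box extent across valid frames
    times the pixel size — the step that buys back lateral resolution
    after the tracking pass.
    """
    return beam_from_coverage(
        trace.max_bbox_extent_px() * pixel_size, wavelength, refractive_index
    )


def plan_acquisition(
    model: TumbleModel,
    beam: BeamGeometry,
    angles_deg: Sequence[float],
    fov_size: Tuple[int, int],
    sample_extent_px: Optional[float] = None,
) -> AcquisitionPlan:
    """Tabulate FoV offsets and focus positions for the given angles."""
    angles = np.asarray(angles_deg, dtype=float)
    if sample_extent_px is not None and min(fov_size) < sample_extent_px:
        raise ValueError(
            f"fov_size {fov_size} smaller than sample extent; "
            f"minimum {math.ceil(sample_extent_px)} px per side required"
        )
    return AcquisitionPlan(
        angles_deg=angles,
        fov_offsets_px=fov_offset(model, angles),
        focus_positions_um=focus_position(model, angles),
        fov_size=tuple(fov_size),
        beam=beam,
    )
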