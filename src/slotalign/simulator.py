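"""Synthetic SLOT acquisition generator.

Renders transmission and fluorescence projections of a weakly absorbing
spherical phantom (a cleared cell spheroid) that may contain a darker
spherical inclusion — the "dark spot" cavities of dead cells seen in
real spheroids.  The sample is embedded off the rotation axis, so its
centre tumbles on a circle: at stage angle ``phi`` the lateral (column)
position is ``a*sin(phi + c) + d`` and the axial offset from the focal
plane is ``a*cos(phi + c)`` — the two sinusoids the tracking algorithm
has to recover.  On top of that deterministic motion the generator
injects per-frame random jitter (the mechanical imperfection the
de-jitter algorithm corrects), angle-dependent defocus blur from the
Gaussian-beam width, additive noise, and optional nuisance artifacts
(cuvette edges, dust specks, background gradient) that the detection
filters must reject.

Every stack comes with full ground truth, so all downstream stages are
testable without an instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .beam_optics import BeamGeometry, beam_radius_at
from .stack import ProjectionStack

__all__ = [
    "PhantomSpec",
    "ArtifactFlags",
    "AcquisitionSpec",
    "GroundTruth",
    "render_projection",
    "simulate_acquisition",
    "attenuation_slice",
]

I0 = 1.0  # unattenuated transmission intensity
_MIN_INTENSITY = 1e-4


@dataclass(frozen=True)
class PhantomSpec:
    """Spherical phantom: weakly absorbing sphere with optional dark inclusion.

    Lengths in µm, attenuation coefficients per µm,
    ``fluorescence_density`` in arbitrary units per µm of path.  The
    inclusion offset is a vector ``(x, y, z)`` in the sample frame
    (x lateral at angle 0, y vertical, z axial at angle 0); it rotates
    rigidly with the sample.  ``inclusion_radius = 0`` gives the
    featureless, homogeneously transparent sample that defeats
    prominent-point jitter correction.
    """

    sphere_radius: float = 400.0
    attenuation: float = 1.5e-3
    inclusion_center_offset: Tuple[float, float, float] = (150.0, 0.0, 40.0)
    inclusion_radius: float = 0.0
    inclusion_attenuation: float = 6.0e-3
    fluorescence_density: float = 1.0e-3

    def __post_init__(self) -> None:
        if not self.sphere_radius > 0:
            raise ValueError("sphere_radius must be positive")
        if self.attenuation < 0 or self.inclusion_attenuation < 0:
            raise ValueError("attenuation coefficients must be non-negative")
        if self.inclusion_radius < 0:
            raise ValueError("inclusion_radius must be non-negative")
        if self.inclusion_radius > 0:
            off = np.linalg.norm(self.inclusion_center_offset)
            if off + self.inclusion_radius > self.sphere_radius:
                raise ValueError("inclusion must lie fully inside the sphere")

    @classmethod
    def with_inclusion(cls, **kwargs) -> "PhantomSpec":
        """Spheroid with the default dark inclusion enabled."""
        kwargs.setdefault("inclusion_radius", 80.0)
        return cls(**kwargs)


@dataclass(frozen=True)
class ArtifactFlags:
    cuvette_edges: bool = False
    dust_specks: bool = False
    background_gradient: bool = False


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and nuisance parameters of one simulated rotation.

    Defaults describe the fast-pass survey scan: 26 frames over 360°,
    full field of view at 36 µm/px, tumble radius 1920 µm.  Frame ``k``
    is taken at ``phi_k = k*360/n_frames`` degrees.  ``axis_offset`` is
    the lateral position of the rotation axis in the frame (µm);
    ``None`` places it at the frame's centre column.  ``jitter_std`` is
    the standard deviation of the i.i.d. Gaussian per-frame displacement
    in µm (applied laterally, and vertically too if ``vertical_jitter``).
    """

    n_frames: int = 26
    frame_shape: Tuple[int, int] = (160, 220)
    pixel_size: float = 36.0
    tumble_amplitude: float = 1920.0
    tumble_phase: float = 0.3
    axis_offset: Optional[float] = None
    axis_tilt_vertical_drift: float = 0.0
    jitter_std: float = 0.0
    vertical_jitter: bool = False
    noise_std: float = 0.0
    beam: Optional[BeamGeometry] = None
    artifacts: ArtifactFlags = field(default_factory=ArtifactFlags)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.jitter_std < 0 or self.noise_std < 0:
            raise ValueError("jitter_std and noise_std must be non-negative")

    @classmethod
    def full_acquisition(cls, **kwargs) -> "AcquisitionSpec":
        """The instrument's full tomographic scan: 800 frames, 500x477 px."""
        kwargs.setdefault("n_frames", 800)
        kwargs.setdefault("frame_shape", (477, 500))
        return cls(**kwargs)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_frames) * 360.0 / self.n_frames

    def axis_offset_um(self) -> float:
        if self.axis_offset is not None:
            return float(self.axis_offset)
        return (self.frame_shape[1] - 1) / 2.0 * self.pixel_size


@dataclass
class GroundTruth:
    """Everything the generator knew: per-frame truth plus tumble parameters."""

    angles_deg: np.ndarray
    lateral_center_px: np.ndarray  # includes jitter (as rendered)
    vertical_center_px: np.ndarray
    axial_offset_um: np.ndarray
    jitter_px: np.ndarray
    jitter_vertical_px: np.ndarray
    amplitude_px: float
    phase: float
    axis_offset_px: float
    amplitude_um: float
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.angles_deg)
        for name in (
            "lateral_center_px",
            "vertical_center_px",
            "axial_offset_um",
            "jitter_px",
            "jitter_vertical_px",
        ):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must equal n_frames")


def _sphere_chords(phantom: PhantomSpec, acq: AcquisitionSpec, angle_deg: float,
                   lateral_center_um: float, vertical_center_um: float):
    """Parallel-ray path lengths through sphere and inclusion, per pixel (µm)."""
    rows, cols = acq.frame_shape
    x = np.arange(cols) * acq.pixel_size  # lateral, µm
    y = np.arange(rows) * acq.pixel_size  # vertical, µm
    dx = x[None, :] - lateral_center_um
    dy = y[:, None] - vertical_center_um

    r2 = phantom.sphere_radius**2 - (dx**2 + dy**2)
    chord_sphere = 2.0 * np.sqrt(np.clip(r2, 0.0, None))

    chord_incl = 0.0
    if phantom.inclusion_radius > 0:
        phi = np.deg2rad(angle_deg)
        ox, oy, oz = phantom.inclusion_center_offset
        lat = ox * np.cos(phi) + oz * np.sin(phi)  # rotates with the sample
        ri2 = phantom.inclusion_radius**2 - ((dx - lat) ** 2 + (dy - oy) ** 2)
        chord_incl = 2.0 * np.sqrt(np.clip(ri2, 0.0, None))
    return chord_sphere, chord_incl


def _apply_artifacts(frame: np.ndarray, acq: AcquisitionSpec, channel: str) -> np.ndarray:
    flags = acq.artifacts
    rows, cols = frame.shape
    dark = channel == "transmission"
    if flags.background_gradient:
        ramp = np.linspace(-0.5, 0.5, cols)[None, :]
        if dark:
            frame = frame * (1.0 + 0.06 * ramp)
        else:
            frame = frame + 0.03 * (ramp + 0.5)
    if flags.cuvette_edges:
        band = np.ones(cols)
        band[2:5] = 0.45
        band[cols - 5 : cols - 2] = 0.45
        if dark:
            frame = frame * band[None, :]
        else:
            frame = frame + 0.4 * (band[None, :] < 1.0)
    if flags.dust_specks:
        rng = np.random.default_rng(acq.seed + 9173)  # static across frames
        for _ in range(3):
            r0 = rng.integers(rows // 8, 7 * rows // 8)
            c0 = rng.integers(cols // 8, 7 * cols // 8)
            rad = int(rng.integers(2, 4))
            rr, cc = np.ogrid[:rows, :cols]
            speck = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
            if dark:
                frame = np.where(speck, frame * 0.3, frame)
            else:
                frame = np.where(speck, frame + 0.5, frame)
    return frame


def render_projection(
    phantom: PhantomSpec,
    acq: AcquisitionSpec,
    angle_deg: float,
    lateral_center_um: float,
    axial_offset_um: float,
    vertical_center_um: Optional[float] = None,
    channel: str = "transmission",
) -> np.ndarray:
    """Render one parallel-beam projection frame.

    Transmission: Beer–Lambert ``I = I0 * exp(-sum(mu * path))`` with
    analytic sphere-chord path lengths.  Fluorescence: the line integral
    of the fluorophore density (zero inside the dead-cell inclusion),
    i.e. inverted contrast relative to transmission.  If ``acq.beam`` is
    set, the frame is blurred with a Gaussian whose sigma follows the
    beam radius at the sample's axial offset (``sigma = w(z)/2``, the
    1/e² radius of a Gaussian beam being two intensity sigmas).
    """
    rows, cols = acq.frame_shape
    if vertical_center_um is None:
        vertical_center_um = (rows - 1) / 2.0 * acq.pixel_size
    span = (cols - 1) * acq.pixel_size
    if (
        lateral_center_um + phantom.sphere_radius < 0
        or lateral_center_um - phantom.sphere_radius > span
    ):
        warnings.warn(
            f"phantom fully outside the frame at angle {angle_deg:.1f} deg",
            stacklevel=2,
        )
    chord_s, chord_i = _sphere_chords(
        phantom, acq, angle_deg, lateral_center_um, vertical_center_um
    )
    if channel == "transmission":
        optical_depth = phantom.attenuation * chord_s + (
            phantom.inclusion_attenuation - phantom.attenuation
        ) * chord_i
        frame = I0 * np.exp(-optical_depth)
    elif channel == "fluorescence":
        frame = phantom.fluorescence_density * (chord_s - chord_i)
    else:
        raise ValueError(f"unknown channel {channel!r}")

    if acq.beam is not None:
        sigma_px = beam_radius_at(acq.beam, axial_offset_um) / (2.0 * acq.pixel_size)
        if sigma_px > 0.05:
            frame = gaussian_filter(frame, sigma_px, mode="nearest")
    return _apply_artifacts(frame, acq, channel)


def simulate_acquisition(
    phantom: PhantomSpec,
    acq: AcquisitionSpec,
    channel: str = "transmission",
) -> Tuple[ProjectionStack, GroundTruth]:
    """Simulate a full rotation; reproducible for a given ``acq.seed``.

    Frame ``k`` at angle ``phi_k``: true lateral centre
    ``a*sin(phi_k + c) + d`` plus Gaussian jitter, axial offset
    ``a*cos(phi_k + c)``, vertical centre drifting by
    ``axis_tilt_vertical_drift`` µm per revolution (plus optional
    vertical jitter).  Additive Gaussian noise of ``noise_std`` relative
    intensity is applied last.
    """
    rng = np.random.default_rng(acq.seed)
    angles = acq.angles_deg
    phi = np.deg2rad(angles)
    a = acq.tumble_amplitude
    c = acq.tumble_phase
    d = acq.axis_offset_um()
    px = acq.pixel_size
    rows, cols = acq.frame_shape

    jitter = rng.normal(0.0, acq.jitter_std, acq.n_frames) if acq.jitter_std else np.zeros(acq.n_frames)
    vjitter = (
        rng.normal(0.0, acq.jitter_std, acq.n_frames)
        if (acq.jitter_std and acq.vertical_jitter)
        else np.zeros(acq.n_frames)
    )
    lateral = a * np.sin(phi + c) + d + jitter
    axial = a * np.cos(phi + c)
    vertical = (
        (rows - 1) / 2.0 * px
        + acq.axis_tilt_vertical_drift * angles / 360.0
        + vjitter
    )

    frames = np.empty((acq.n_frames, rows, cols))
    caught: list = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        for k in range(acq.n_frames):
            frames[k] = render_projection(
                phantom, acq, angles[k], lateral[k], axial[k], vertical[k], channel
            )
        caught = [str(w.message) for w in wrec]
    if acq.noise_std:
        frames = frames + rng.normal(0.0, acq.noise_std, frames.shape)
    if channel == "transmission":
        frames = np.clip(frames, _MIN_INTENSITY, I0)
    else:
        frames = np.clip(frames, 0.0, None)

    stack = ProjectionStack(
        frames=frames,
        angles_deg=angles,
        pixel_size=px,
        channel=channel,
        meta={"simulated": True, "seed": acq.seed, "warnings": caught},
    )
    truth = GroundTruth(
        angles_deg=angles,
        lateral_center_px=lateral / px,
        vertical_center_px=vertical / px,
        axial_offset_um=axial,
        jitter_px=jitter / px,
        jitter_vertical_px=vjitter / px,
        amplitude_px=a / px,
        phase=c,
        axis_offset_px=d / px,
        amplitude_um=a,
        warnings=caught,
    )
    return stack, truth


def attenuation_slice(
    phantom: PhantomSpec,
    pixel_size: float,
    size: int,
    vertical_offset_um: float = 0.0,
    tumble_amplitude: float = 0.0,
    tumble_phase: float = 0.0,
) -> np.ndarray:
    """Ground-truth attenuation map of the phantom slice at a given height.

    Returns a ``(size, size)`` µ map (per µm) of the horizontal plane
    ``vertical_offset_um`` above the sphere centre, on the grid a
    filtered back-projection of the acquisition reconstructs: the grid
    centre is the rotation axis, rows are axial z and columns lateral x.
    A tumbling sample (amplitude ``a``, phase ``c``) sits off-axis at
    ``(x, z) = (a*sin(c), a*cos(c))``, its angle-0 position; the
    inclusion is placed relative to that.
    """
    ctr = (size - 1) / 2.0
    sx = tumble_amplitude * np.sin(tumble_phase)
    sz = tumble_amplitude * np.cos(tumble_phase)
    x = (np.arange(size) - ctr) * pixel_size - sx  # lateral, sample frame
    z = (np.arange(size) - ctr) * pixel_size - sz  # axial, sample frame
    xx = x[None, :]
    zz = z[:, None]
    mu = np.zeros((size, size))
    cross2 = phantom.sphere_radius**2 - vertical_offset_um**2
    if cross2 > 0:
        mu[xx**2 + zz**2 <= cross2] = phantom.attenuation
    if phantom.inclusion_radius > 0:
        ox, oy, oz = phantom.inclusion_center_offset
        dyi = oy - vertical_offset_um
        ci2 = phantom.inclusion_radius**2 - dyi**2
        if ci2 > 0:
            mask = (xx - ox) ** 2 + (zz - oz) ** 2 <= ci2
            mu[mask] = phantom.inclusion_attenuation
    return mu
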