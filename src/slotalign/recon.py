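"""Sinogram extraction, filtered back-projection and quality metrics.

The effect of jitter correction is judged the way an operator would:
pick the detector row that crosses a recognizable structure, read its
sinogram out of the stack, reconstruct the slice by parallel-beam
filtered back-projection (FBP) before and after correction, and compare
sharpness and fidelity.  The FBP here is the textbook pipeline: per-
angle ``-log(I/I0)`` attenuation projections, Ram-Lak ramp filtering in
the frequency domain, and back-projection with linear interpolation
onto a square grid whose rotation centre is the detector centre column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .stack import ProjectionStack

__all__ = [
    "Sinogram",
    "extract_sinogram",
    "fbp_reconstruct",
    "sinogram_to_attenuation",
    "sharpness_score",
    "reconstruction_circle",
    "masked_pearson",
    "compare_before_after",
]


@dataclass
class Sinogram:
    """Rows = projection angles, columns = detector (lateral) positions."""

    data: np.ndarray
    angles_deg: np.ndarray
    source_row: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.data.ndim != 2 or len(self.data) != len(self.angles_deg):
            raise ValueError("one sinogram row per angle required")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")


def extract_sinogram(stack: ProjectionStack, row: int) -> Sinogram:
    """Row ``row`` of frame ``k`` becomes sinogram row ``k``; intensities kept."""
    rows = stack.frame_shape[0]
    if not 0 <= row < rows:
        raise ValueError(f"row {row} outside frame rows [0, {rows})")
    return Sinogram(
        data=stack.frames[:, row, :].copy(),
        angles_deg=stack.angles_deg.copy(),
        source_row=row,
    )


def sinogram_to_attenuation(
    sino: Sinogram, i0_frac: float = 0.05, fill_threshold: float = 5e-3
) -> np.ndarray:
    """Per-angle ``-log(I/I0)`` with I0 from the outermost detector columns.

    I0 is the median of the outermost ``i0_frac`` columns on each side
    of every row (background air/medium).  Pixels at or below
    ``fill_threshold`` are vacated fill borders from integer shifting,
    not physical attenuation; they are treated as background (zero).
    """
    data = sino.data
    n_edge = max(int(round(i0_frac * data.shape[1] / 2.0)), 1)
    edges = np.concatenate([data[:, :n_edge], data[:, -n_edge:]], axis=1)
    i0 = np.median(edges, axis=1, keepdims=True)
    i0 = np.clip(i0, 1e-6, None)
    p = -np.log(np.clip(data, 1e-6, None) / i0)
    p[data <= fill_threshold] = 0.0
    return np.clip(p, 0.0, None)


def _ramp_filter(projections: np.ndarray) -> np.ndarray:
    """Ram-Lak filter each row (detector axis) in the frequency domain."""
    n = projections.shape[1]
    pad = 1 << max(int(np.ceil(np.log2(2 * n))), 6)
    freqs = np.fft.fftfreq(pad)
    ramp = np.abs(freqs)
    spectrum = np.fft.fft(projections, pad, axis=1) * ramp[None, :]
    return np.real(np.fft.ifft(spectrum, axis=1))[:, :n]


def fbp_reconstruct(
    sino: Sinogram,
    i0_frac: float = 0.05,
    is_attenuation: bool = False,
) -> np.ndarray:
    """Filtered back-projection of one sinogram onto a square grid.

    Requires at least 8 angles spanning at least 180°.  The grid side
    equals the detector count and the rotation centre is the detector
    centre column ``(W - 1) / 2``.  Set ``is_attenuation`` when the
    sinogram already holds line integrals instead of transmitted
    intensities.
    """
    angles = sino.angles_deg
    if len(angles) < 8:
        raise ValueError(f"need at least 8 angles, got {len(angles)}")
    step = float(np.mean(np.diff(angles)))
    span = float(angles[-1] - angles[0]) + step
    if span < 180.0 - 1e-6:
        raise ValueError(f"angle span {span:.1f} deg is below the 180 deg minimum")

    p = sino.data if is_attenuation else sinogram_to_attenuation(sino, i0_frac)
    filtered = _ramp_filter(p)

    n_det = p.shape[1]
    center = (n_det - 1) / 2.0
    coords = np.arange(n_det) - center
    xx = coords[None, :]  # lateral (columns)
    yy = coords[:, None]  # axial (rows)
    recon = np.zeros((n_det, n_det))
    det_idx = np.arange(n_det, dtype=float)
    for row, angle in zip(filtered, angles):
        phi = np.deg2rad(angle)
        t = xx * np.cos(phi) + yy * np.sin(phi) + center
        recon += np.interp(t.ravel(), det_idx, row, left=0.0, right=0.0).reshape(
            n_det, n_det
        )
    return recon * (np.pi / len(angles))


def sharpness_score(image: np.ndarray) -> float:
    """Tenengrad focus measure: mean squared Sobel gradient magnitude.

    Invariant to additive constants; strictly decreases under blur of a
    structured image; zero for a constant image.
    """
    image = np.asarray(image, dtype=float)
    gx = ndi.sobel(image, axis=1)
    gy = ndi.sobel(image, axis=0)
    return float(np.mean(gx**2 + gy**2))


def reconstruction_circle(size: int) -> np.ndarray:
    """Mask of the inscribed circle, inside which FBP values are trustworthy."""
    ctr = (size - 1) / 2.0
    yy, xx = np.mgrid[:size, :size]
    return (xx - ctr) ** 2 + (yy - ctr) ** 2 <= ctr**2


def masked_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two images over a boolean mask."""
    av = np.asarray(a, dtype=float)[mask]
    bv = np.asarray(b, dtype=float)[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


def compare_before_after(
    stack_raw: ProjectionStack,
    stack_corrected: ProjectionStack,
    row: int,
    ground_truth_slice: np.ndarray = None,
) -> dict:
    """Reconstruct the same row from both stacks and quantify the gain.

    Reports Tenengrad sharpness for both reconstructions and, when a
    ground-truth attenuation slice is supplied, the Pearson correlation
    with it inside the inscribed circle (the outer FBP ring artifact is
    masked out).  Positive deltas mean the correction helped.
    """
    if stack_raw.frame_shape != stack_corrected.frame_shape or len(
        stack_raw
    ) != len(stack_corrected):
        raise ValueError("stacks must share geometry")
    rec_raw = fbp_reconstruct(extract_sinogram(stack_raw, row))
    rec_cor = fbp_reconstruct(extract_sinogram(stack_corrected, row))
    mask = reconstruction_circle(rec_raw.shape[0])
    report = {
        "row": int(row),
        "sharpness_raw": sharpness_score(rec_raw),
        "sharpness_corrected": sharpness_score(rec_cor),
    }
    report["sharpness_delta"] = (
        report["sharpness_corrected"] - report["sharpness_raw"]
    )
    if ground_truth_slice is not None:
        gt = np.asarray(ground_truth_slice, dtype=float)
        if gt.shape != rec_raw.shape:
            raise ValueError(
                f"ground-truth slice shape {gt.shape} != reconstruction {rec_raw.shape}"
            )
        report["correlation_raw"] = masked_pearson(rec_raw, gt, mask)
        report["correlation_corrected"] = masked_pearson(rec_cor, gt, mask)
        report["correlation_delta"] = (
            report["correlation_corrected"] - report["correlation_raw"]
        )
    return report
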