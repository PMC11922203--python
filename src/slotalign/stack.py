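"""Projection-stack container shared by every processing stage.

Conventions used throughout the package:

* frames are indexed ``(row, col)`` with the origin at the top left;
* the **column** axis is the lateral/detector axis (the scan "y
  direction" of the instrument) along which the tumbling sample moves
  and along which sinogram rows are read;
* the **row** axis is vertical (parallel to the rotation axis);
* intensities are floats in ``[0, 1]`` with ``I0 = 1`` for the
  unattenuated transmission background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["ProjectionStack"]


@dataclass
class ProjectionStack:
    """Ordered projection frames plus acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Projection images, float intensities.
    angles_deg : ndarray, shape (n_frames,)
        Rotation-stage angle of each frame, degrees.
    pixel_size : float
        Lateral pixel pitch, µm per pixel.
    channel : {"transmission", "fluorescence"}
    roi : tuple or None
        Optional ``(row0, col0, row1, col1)`` half-open rectangle marking
        the sub-area of the full scan field this stack was taken from.
    meta : dict
        Free-form provenance (simulator spec, acquisition notes).
    """

    frames: np.ndarray
    angles_deg: np.ndarray
    pixel_size: float
    channel: str = "transmission"
    roi: Optional[tuple] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if len(self.frames) != len(self.angles_deg):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.angles_deg)} angles"
            )
        if len(self.frames) < 2:
            raise ValueError("a projection stack needs at least 2 frames")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.channel not in ("transmission", "fluorescence"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.roi is not None:
            r0, c0, r1, c1 = self.roi
            rows, cols = self.frame_shape
            if not (0 <= r0 < r1 and 0 <= c0 < c1):
                raise ValueError(f"malformed roi {self.roi}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]

    def copy(self, frames: Optional[np.ndarray] = None) -> "ProjectionStack":
        """Shallow metadata copy, optionally with replacement frames."""
        return replace(
            self,
            frames=np.array(self.frames if frames is None else frames),
            angles_deg=self.angles_deg.copy(),
            meta=dict(self.meta),
        )
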