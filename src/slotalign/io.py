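"""Stack I/O and pipeline orchestration.

Stacks travel as multipage grayscale TIFF (8- or 16-bit, one page per
frame) plus a JSON sidecar holding the per-frame rotation angles, the
pixel size, the channel and free-form provenance.  Angles always live
in the sidecar — never in filenames; a missing sidecar falls back to a
uniform 0–360° schedule with a loud warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile

import sys

from . import recon, simulator, tracking
from . import dejitter as _dj_import  # noqa: F401  (ensures the submodule loads)

# the package re-exports a function named `dejitter`; always talk to the module
dj = sys.modules[__package__ + ".dejitter"]
from .stack import ProjectionStack

__all__ = [
    "StackSidecar",
    "read_stack",
    "write_stack",
    "run_pipeline",
    "SidecarError",
]

logger = logging.getLogger("slotalign")

_UINT16_MAX = 65535


class SidecarError(ValueError):
    """Malformed or inconsistent sidecar metadata."""


@dataclass
class StackSidecar:
    """JSON sidecar accompanying a stack TIFF."""

    angles_deg: list
    pixel_size_um: float
    channel: str = "transmission"
    roi: Optional[list] = None
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "StackSidecar":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise SidecarError(f"malformed sidecar JSON {path}: {exc}") from exc
        unknown = set(payload) - {
            "angles_deg",
            "pixel_size_um",
            "channel",
            "roi",
            "provenance",
        }
        if unknown:
            raise SidecarError(f"unknown sidecar keys {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        )


def read_stack(tiff_path, sidecar_path=None) -> ProjectionStack:
    """Load a stack; intensities normalized to [0, 1] preserving scale.

    8-bit pages divide by 255, 16-bit by 65535, so the recorded I0 of a
    written stack maps back to 1.0 within one quantization step.
    """
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.dtype == np.uint8:
        frames = pages.astype(float) / 255.0
    elif pages.dtype == np.uint16:
        frames = pages.astype(float) / _UINT16_MAX
    else:
        raise ValueError(
            f"unsupported TIFF bit depth {pages.dtype}; 8- or 16-bit grayscale required"
        )
    if sidecar_path is not None and Path(sidecar_path).exists():
        sidecar = StackSidecar.from_json(sidecar_path)
        if len(sidecar.angles_deg) != len(frames):
            raise SidecarError(
                f"{len(frames)} TIFF pages but {len(sidecar.angles_deg)} angles in sidecar"
            )
        angles = np.asarray(sidecar.angles_deg, dtype=float)
        pixel_size = float(sidecar.pixel_size_um)
        channel = sidecar.channel
        roi = tuple(sidecar.roi) if sidecar.roi else None
        meta = dict(sidecar.provenance)
    else:
        warnings.warn(
            "no sidecar found: assuming uniform angles over [0, 360) and "
            "pixel size 1 µm",
            stacklevel=2,
        )
        angles = np.arange(len(frames)) * 360.0 / len(frames)
        pixel_size, channel, roi, meta = 1.0, "transmission", None, {}
    return ProjectionStack(
        frames=frames,
        angles_deg=angles,
        pixel_size=pixel_size,
        channel=channel,
        roi=roi,
        meta=meta,
    )


def write_stack(stack: ProjectionStack, tiff_path, sidecar_path) -> Tuple[Path, Path]:
    """Write a stack as 16-bit multipage TIFF plus JSON sidecar.

    Output bytes are deterministic for identical inputs (no timestamps,
    fixed tag layout), so reruns are directly diffable.
    """
    if len(stack) == 0:
        raise ValueError("refusing to write an empty stack")
    tiff_path, sidecar_path = Path(tiff_path), Path(sidecar_path)
    data = np.clip(stack.frames, 0.0, 1.0)
    pages = np.round(data * _UINT16_MAX).astype(np.uint16)
    tifffile.imwrite(tiff_path, pages, photometric="minisblack")
    StackSidecar(
        angles_deg=[float(a) for a in stack.angles_deg],
        pixel_size_um=float(stack.pixel_size),
        channel=stack.channel,
        roi=list(stack.roi) if stack.roi else None,
        provenance=_jsonable(stack.meta),
    ).to_json(sidecar_path)
    return tiff_path, sidecar_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# --------------------------------------------------------------------------
# pipeline


_TOP_KEYS = {
    "seed",
    "outdir",
    "channel",
    "phantom",
    "acquisition",
    "tracking",
    "dejitter",
    "reconstruct",
}


def _check_keys(section: str, payload: dict, allowed: set) -> None:
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")


def run_pipeline(config: dict, outdir=None) -> dict:
    """Offline orchestration: simulate → track → plan → dejitter → reconstruct.

    ``config`` mirrors the YAML accepted by the ``run`` subcommand; all
    randomness flows from its single ``seed``.  Every stage writes its
    artifacts under ``outdir`` and contributes to the returned summary,
    which is byte-identical across reruns with the same config.
    """
    _check_keys("top-level", config, _TOP_KEYS)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "slotalign_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    channel = config.get("channel", "transmission")
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    summary: dict = {"config_hash": digest, "seed": seed, "stages": {}}
    t_start = time.perf_counter()

    phantom_cfg = dict(config.get("phantom", {}))
    include_inclusion = phantom_cfg.pop("inclusion", True)
    phantom = (
        simulator.PhantomSpec.with_inclusion(**phantom_cfg)
        if include_inclusion
        else simulator.PhantomSpec(**phantom_cfg)
    )
    acq_cfg = dict(config.get("acquisition", {}))
    acq_cfg.setdefault("seed", seed)
    if "frame_shape" in acq_cfg:
        acq_cfg["frame_shape"] = tuple(acq_cfg["frame_shape"])
    acq = simulator.AcquisitionSpec(**acq_cfg)

    stack, truth = simulator.simulate_acquisition(phantom, acq, channel)
    write_stack(stack, outdir / "stack.tif", outdir / "stack.json")
    summary["stages"]["simulate"] = {
        "n_frames": len(stack),
        "frame_shape": list(stack.frame_shape),
        "amplitude_px": truth.amplitude_px,
    }
    logger.info("simulate: %d frames (%.2fs)", len(stack), time.perf_counter() - t_start)

    trk_cfg = dict(config.get("tracking", {}))
    _check_keys("tracking", trk_cfg, {"wavelength", "refractive_index"})
    t0 = time.perf_counter()
    trace = tracking.track_stack(stack)
    model = tracking.fit_tumble(trace, stack.pixel_size)
    _write_trace_csv(trace, outdir / "trace.csv")
    (outdir / "tumble_model.json").write_text(
        json.dumps(asdict(model), indent=2, sort_keys=True) + "\n"
    )
    beam = tracking.beam_for_sample(
        trace,
        stack.pixel_size,
        trk_cfg.get("wavelength", 0.532),
        trk_cfg.get("refractive_index", 1.54),
    )
    plan = tracking.plan_acquisition(
        model, beam, stack.angles_deg, stack.frame_shape
    )
    _write_plan_csv(plan, outdir / "plan.csv")
    summary["stages"]["track"] = {
        "valid_frames": int(trace.valid_mask.sum()),
        "amplitude_px": model.amplitude,
        "axis_offset_px": model.axis_offset,
        "residual_rmse_px": model.residual_rmse,
        "lateral_resolution_um": beam.lateral_resolution,
    }
    logger.info("track: fit a=%.2f px (%.2fs)", model.amplitude, time.perf_counter() - t0)

    dj_cfg = dict(config.get("dejitter", {}))
    mode = dj_cfg.pop("mode", "sine_fit")
    vertical = dj_cfg.pop("vertical", False)
    max_iterations = dj_cfg.pop("max_iterations", 10)
    seg = dj.SegmentationConfig(**dj_cfg)
    t0 = time.perf_counter()
    corrected, shifts, report = dj.dejitter(
        stack, seg, mode=mode, vertical=vertical, max_iterations=max_iterations
    )
    write_stack(corrected, outdir / "corrected.tif", outdir / "corrected.json")
    _write_shifts_csv(shifts, outdir / "shifts.csv")
    (outdir / "dejitter_report.json").write_text(
        json.dumps(
            {
                "iterations": report.iterations,
                "jitter_error_per_iteration": report.jitter_error_per_iteration,
                "final_max_abs_residual": report.final_max_abs_residual,
                "mode": report.mode,
                "vertical_applied": report.vertical_applied,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    summary["stages"]["dejitter"] = {
        "iterations": report.iterations,
        "final_max_abs_residual_px": report.final_max_abs_residual,
    }
    logger.info("dejitter: %d iterations (%.2fs)", report.iterations, time.perf_counter() - t0)

    rec_cfg = dict(config.get("reconstruct", {}))
    _check_keys("reconstruct", rec_cfg, {"row"})
    row = int(rec_cfg.get("row", stack.frame_shape[0] // 2))
    gt = simulator.attenuation_slice(
        phantom,
        stack.pixel_size,
        stack.frame_shape[1],
        vertical_offset_um=(row - (stack.frame_shape[0] - 1) / 2.0) * stack.pixel_size,
        tumble_amplitude=acq.tumble_amplitude,
        tumble_phase=acq.tumble_phase,
    )
    t0 = time.perf_counter()
    comparison = recon.compare_before_after(stack, corrected, row, gt)
    (outdir / "comparison.json").write_text(
        json.dumps(comparison, indent=2, sort_keys=True) + "\n"
    )
    summary["stages"]["reconstruct"] = comparison
    logger.info("reconstruct row %d (%.2fs)", row, time.perf_counter() - t0)

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


def _write_trace_csv(trace: tracking.DetectionTrace, path) -> None:
    lines = ["frame,angle_deg,x_px,y_px,valid,reason"]
    for k, (angle, det) in enumerate(zip(trace.angles_deg, trace.detections)):
        x, y = det.center if det.center else ("", "")
        lines.append(f"{k},{angle},{x},{y},{int(det.valid)},{det.reason}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_plan_csv(plan: tracking.AcquisitionPlan, path) -> None:
    lines = ["angle_deg,fov_offset_px,focus_um"]
    for row in plan.to_rows():
        lines.append(
            f"{row['angle_deg']},{row['fov_offset_px']},{row['focus_um']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _write_shifts_csv(shifts: dj.ShiftTable, path) -> None:
    lines = ["frame,dx,dy"]
    for k, (dx, dy) in enumerate(zip(shifts.dx, shifts.dy)):
        lines.append(f"{k},{int(dx)},{int(dy)}")
    Path(path).write_text("\n".join(lines) + "\n")
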