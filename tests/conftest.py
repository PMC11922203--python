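"""Shared fixtures: small synthetic scenes, cached per session."""

from __future__ import annotations

from functools import lru_cache

import pytest
from hypothesis import HealthCheck, settings

import slotalign as sa

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@lru_cache(maxsize=16)
def _jitter_scene(seed: int, jitter_px: float, inclusion: bool, n_frames: int = 200,
                  vertical: bool = False, drift_um: float = 0.0):
    """Zoomed-FoV dejitter scenario: 8 µm/px, 160x160 px, 400 µm sphere."""
    px = 8.0
    phantom = (
        sa.PhantomSpec.with_inclusion() if inclusion else sa.PhantomSpec()
    )
    acq = sa.AcquisitionSpec(
        n_frames=n_frames,
        frame_shape=(160, 160),
        pixel_size=px,
        tumble_amplitude=80.0,
        tumble_phase=0.3,
        jitter_std=jitter_px * px,
        vertical_jitter=vertical,
        axis_tilt_vertical_drift=drift_um,
        noise_std=0.01,
        seed=seed,
    )
    stack, truth = sa.simulate_acquisition(phantom, acq)
    return phantom, acq, stack, truth


@pytest.fixture(scope="session")
def jitter_scene():
    """Factory for cached jittered acquisition scenes."""
    return _jitter_scene


@pytest.fixture(scope="session")
def fastpass_scene():
    """Fast-pass survey scan: 26 frames, full FoV, tumbling 1920 µm sample."""
    beam = sa.beam_from_coverage(18000.0, 0.532, 1.54)
    phantom = sa.PhantomSpec()
    acq = sa.AcquisitionSpec(beam=beam, seed=1)
    stack, truth = sa.simulate_acquisition(phantom, acq)
    return phantom, acq, stack, truth


@pytest.fixture(scope="session")
def artifact_fastpass_scene():
    """Fast pass with cuvette edges, dust and a background gradient enabled."""
    beam = sa.beam_from_coverage(18000.0, 0.532, 1.54)
    phantom = sa.PhantomSpec()
    acq = sa.AcquisitionSpec(
        beam=beam,
        seed=2,
        noise_std=0.01,
        artifacts=sa.ArtifactFlags(
            cuvette_edges=True, dust_specks=True, background_gradient=True
        ),
    )
    stack, truth = sa.simulate_acquisition(phantom, acq)
    return phantom, acq, stack, truth
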