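"""De-jitter primitives and the iterative correction loop."""

import numpy as np
import pytest

import slotalign as sa
from slotalign.dejitter import (
    SegmentationConfig,
    ShiftTable,
    _round_half_away,
    binarize,
    measure_centroids,
    rolling_ball_background,
)


class TestRollingBall:
    def test_flat_frame_becomes_zero(self):
        assert np.allclose(rolling_ball_background(np.full((32, 32), 0.7), 10.0), 0.0)

    def test_ramp_removed_blob_kept(self):
        yy, xx = np.mgrid[:64, :64]
        ramp = 0.3 + 0.004 * xx
        blob = 0.4 * np.exp(-((xx - 30) ** 2 + (yy - 30) ** 2) / (2 * 2.0**2))
        out = rolling_ball_background(ramp + blob, 20.0)
        # judge the ramp removal away from the blob and from the frame border,
        # where the ball cannot roll past the edge
        interior = np.zeros_like(ramp, bool)
        interior[21:-21, 21:-21] = True  # ball radius sets the edge zone
        far = ((xx - 30) ** 2 + (yy - 30) ** 2 > 100) & interior
        assert out[30, 30] - np.median(out[far]) == pytest.approx(0.4, abs=0.06)
        # the background VARIATION is removed (a constant tangential gap of
        # the ball under a slope is harmless to later thresholding)
        assert np.ptp(out[far]) < 0.05 * np.ptp(ramp + blob)

    def test_large_radius_approaches_global_min_subtraction(self):
        yy, xx = np.mgrid[:64, :64]
        blob = 0.4 * np.exp(-((xx - 30) ** 2 + (yy - 30) ** 2) / (2 * 2.0**2))
        out = rolling_ball_background(0.3 + blob, 60.0)
        far = (xx - 30) ** 2 + (yy - 30) ** 2 > 100
        assert np.median(out[far]) == pytest.approx(0.0, abs=1e-6)
        assert out[30, 30] == pytest.approx(0.4, abs=0.02)

    def test_radius_exceeding_frame_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            rolling_ball_background(np.zeros((32, 32)), 100.0)


class TestBinarize:
    @pytest.mark.parametrize("method", ["otsu", "gmm", "canny_fill"])
    def test_two_valued_frame_exact_mask(self, method):
        frame = np.full((60, 60), 0.2)
        frame[20:40, 15:35] = 0.8
        mask = binarize(frame, method)
        np.testing.assert_array_equal(mask, frame == 0.8)

    def test_gmm_threshold_near_mixture_crossover(self):
        """Equal-variance 0.3/0.7 mixture: crossover near the midpoint."""
        rng = np.random.default_rng(0)
        half = rng.random((80, 80)) < 0.5
        frame = np.where(
            half, rng.normal(0.3, 0.05, (80, 80)), rng.normal(0.7, 0.05, (80, 80))
        )
        from slotalign.dejitter import _gmm_threshold

        threshold = _gmm_threshold(np.clip(frame, 0, 1).ravel(), 0)
        assert 0.45 <= threshold <= 0.55

    def test_constant_frame_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize(np.full((16, 16), 0.5), "otsu")
        assert not mask.any()


class TestSegmentAndCentroid:
    def test_specks_removed_disk_kept(self):
        mask = np.zeros((64, 64), bool)
        yy, xx = np.mgrid[:64, :64]
        mask[(xx - 30) ** 2 + (yy - 30) ** 2 <= 64] = True
        for r, c in [(2, 2), (5, 60), (60, 5)]:
            mask[r : r + 1, c : c + 2] = True
        region = sa.segment_object(mask, SegmentationConfig(min_object_area=10))
        rr, cc = np.nonzero(region)
        assert rr.min() > 20 and cc.min() > 20  # only the disk survives

    def test_equal_area_tie_breaks_to_top_left(self):
        mask = np.zeros((20, 20), bool)
        mask[2:6, 2:6] = True
        mask[10:14, 10:14] = True
        region = sa.segment_object(mask, SegmentationConfig(min_object_area=4))
        rr, cc = np.nonzero(region)
        assert (rr.min(), cc.min()) == (2, 2)

    def test_empty_mask_yields_absent(self):
        assert sa.segment_object(np.zeros((16, 16), bool)) is None

    def test_l_shape_centroid_vs_brute_force(self):
        """Five-pixel L: centroid is the plain mean of member coordinates."""
        pixels = [(0, 0), (1, 0), (2, 0), (2, 1), (2, 2)]
        mask = np.zeros((4, 4), bool)
        for r, c in pixels:
            mask[r, c] = True
        x, y = sa.object_centroid(mask, "centroid")
        assert (x, y) == (
            sum(c for _, c in pixels) / 5.0,  # 0.6
            sum(r for r, _ in pixels) / 5.0,  # 1.4
        )
        assert sa.object_centroid(mask, "bbox_center") == (1.0, 1.0)

    def test_symmetric_disk_modes_agree(self):
        mask = np.zeros((41, 41), bool)
        yy, xx = np.mgrid[:41, :41]
        mask[(xx - 20) ** 2 + (yy - 20) ** 2 <= 81] = True
        assert sa.object_centroid(mask, "centroid") == pytest.approx((20.0, 20.0))
        assert sa.object_centroid(mask, "bbox_center") == (20.0, 20.0)

    def test_single_pixel_both_modes(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 5] = True
        assert sa.object_centroid(mask, "centroid") == (5.0, 3.0)
        assert sa.object_centroid(mask, "bbox_center") == (5.0, 3.0)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="empty"):
            sa.object_centroid(np.zeros((4, 4), bool))


class TestCrop:
    def make_stack(self, rows=477, cols=60):
        frames = np.random.default_rng(0).random((4, rows, cols))
        return sa.ProjectionStack(
            frames=frames, angles_deg=np.arange(4) * 90.0, pixel_size=1.0
        )

    def test_row_arithmetic(self):
        out = sa.crop_to_object(self.make_stack(), (100, 150), margin_px=10)
        assert out.frame_shape == (71, 60)

    def test_margin_zero_at_edge_is_noop_on_that_side(self):
        out = sa.crop_to_object(self.make_stack(rows=100), (0, 49), margin_px=0)
        assert out.frame_shape == (50, 60)
        np.testing.assert_array_equal(out.frames, self.make_stack(rows=100).frames[:, :50])

    def test_cropping_preserves_lateral_centroids(self, jitter_scene):
        """Row cropping must not move column centroids."""
        _, _, stack, _ = jitter_scene(1, 3.0, True, n_frames=20)
        cfg = SegmentationConfig()
        before = measure_centroids(stack, cfg)
        cropped = sa.crop_to_object(stack, (30, 130), margin_px=5)
        after = measure_centroids(cropped, cfg)
        np.testing.assert_allclose(before[:, 0], after[:, 0], atol=0.2)

    def test_empty_crop_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sa.crop_to_object(self.make_stack(), (200, 100), margin_px=0)


class TestComputeShifts:
    def test_rounding_half_away_from_zero(self):
        np.testing.assert_array_equal(
            _round_half_away(np.array([-3.4, -3.5, 3.4, 3.5, 0.5, -0.5])),
            [-3, -4, 3, 4, 1, -1],
        )

    def test_centroids_on_the_sine_need_no_shift(self):
        angles = np.arange(26) * 360.0 / 26
        x = 30.0 * np.sin(np.deg2rad(angles) + 0.2) + 60.0
        xy = np.column_stack([x, np.full(26, 40.0)])
        shifts, _ = compute_shifts_helper(xy, angles)
        assert np.all(shifts.dx == 0)
        assert np.all(shifts.dy == 0)

    def test_displaced_centroid_shifted_back(self):
        """A centroid 3.4 px right of the fitted curve gets dx = -3."""
        angles = np.arange(200) * 1.8
        x = 30.0 * np.sin(np.deg2rad(angles) + 0.2) + 60.0
        x[7] += 3.4
        xy = np.column_stack([x, np.full(200, 40.0)])
        shifts, _ = compute_shifts_helper(xy, angles)
        assert shifts.dx[7] == -3

    def test_center_fit_targets_middle_column(self):
        """Constant centroids at column 30 of a 100-wide frame: dx = +20."""
        angles = np.arange(26) * 360.0 / 26
        xy = np.column_stack([np.full(26, 30.0), np.full(26, 40.0)])
        shifts, _ = compute_shifts_helper(xy, angles, mode="center_fit")
        assert np.all(shifts.dx == 20)

    def test_nan_centroids_get_zero_shift(self):
        angles = np.arange(26) * 360.0 / 26
        x = 30.0 * np.sin(np.deg2rad(angles)) + 60.0
        xy = np.column_stack([x, np.full(26, 40.0)])
        xy[3] = np.nan
        shifts, _ = compute_shifts_helper(xy, angles)
        assert shifts.dx[3] == 0


def compute_shifts_helper(xy, angles, mode="sine_fit"):
    return sa.compute_shifts(
        xy, angles, mode=mode, frame_shape=(80, 100)
    )


class TestApplyShifts:
    def make_stack(self):
        frames = np.random.default_rng(1).random((3, 20, 30))
        return sa.ProjectionStack(
            frames=frames, angles_deg=np.arange(3) * 120.0, pixel_size=1.0
        )

    def test_zero_shift_bit_identical(self):
        stack = self.make_stack()
        out = sa.apply_shifts(
            stack, ShiftTable(np.zeros(3, int), np.zeros(3, int))
        )
        assert np.array_equal(out.frames, stack.frames)

    def test_positive_dx_matches_index_oracle(self):
        stack = self.make_stack()
        out = sa.apply_shifts(
            stack, ShiftTable(np.array([2, 0, -3]), np.zeros(3, int), fill_value=0.5)
        )
        np.testing.assert_array_equal(out.frames[0][:, 2:], stack.frames[0][:, :-2])
        assert np.all(out.frames[0][:, :2] == 0.5)
        np.testing.assert_array_equal(out.frames[2][:, :-3], stack.frames[2][:, 3:])
        assert np.all(out.frames[2][:, -3:] == 0.5)

    def test_translation_conserves_interior_mass(self):
        stack = self.make_stack()
        out = sa.apply_shifts(
            stack, ShiftTable(np.array([4, 4, 4]), np.array([1, 1, 1]))
        )
        assert out.frames[0][1:, 4:].sum() == pytest.approx(
            stack.frames[0][:-1, :-4].sum()
        )

    def test_excessive_shift_rejected(self):
        stack = self.make_stack()
        with pytest.raises(ValueError, match="extent"):
            sa.apply_shifts(
                stack, ShiftTable(np.array([30, 0, 0]), np.zeros(3, int))
            )

    def test_length_mismatch_rejected(self):
        stack = self.make_stack()
        with pytest.raises(ValueError, match="shifts"):
            sa.apply_shifts(stack, ShiftTable(np.zeros(5, int), np.zeros(5, int)))


class TestDejitterLoop:
    def test_jitter_free_stack_terminates_immediately(self, jitter_scene):
        _, _, stack, _ = jitter_scene(4, 0.0, True, n_frames=26)
        corrected, shifts, report = sa.dejitter(stack, SegmentationConfig())
        assert report.iterations == 1
        assert np.all(shifts.dx == 0)
        assert np.array_equal(corrected.frames, stack.frames)

    def test_corrected_stack_rerun_is_idempotent(self, jitter_scene):
        _, _, stack, _ = jitter_scene(5, 3.0, True, n_frames=60)
        corrected, _, _ = sa.dejitter(stack, SegmentationConfig())
        _, shifts2, report2 = sa.dejitter(corrected, SegmentationConfig())
        assert report2.iterations == 1
        assert np.all(np.abs(shifts2.dx) <= 1)

    def test_closed_loop_recovers_injected_jitter(self, jitter_scene):
        _, _, stack, truth = jitter_scene(6, 3.0, False, n_frames=100)
        corrected, shifts, report = sa.dejitter(stack, SegmentationConfig())
        target = -np.round(truth.jitter_px).astype(int)
        assert np.mean(np.abs(shifts.dx - target) <= 1) >= 0.95
        assert report.final_max_abs_residual <= 1.0

    def test_jitter_error_non_increasing(self, jitter_scene):
        _, _, stack, _ = jitter_scene(7, 5.0, True, n_frames=100)
        _, _, report = sa.dejitter(stack, SegmentationConfig())
        errors = report.jitter_error_per_iteration
        assert all(b <= a + 0.25 for a, b in zip(errors, errors[1:]))

    def test_vertical_drift_and_jitter_corrected(self, jitter_scene):
        _, _, stack, truth = jitter_scene(
            8, 3.0, True, n_frames=100, vertical=True, drift_um=40.0
        )
        _, shifts, report = sa.dejitter(
            stack, SegmentationConfig(), vertical=True
        )
        target = -np.round(truth.jitter_vertical_px).astype(int)
        assert np.mean(np.abs(shifts.dy - target) <= 1) >= 0.95
        assert report.vertical_applied

    def test_center_fit_moves_sample_to_frame_center(self, jitter_scene):
        _, _, stack, _ = jitter_scene(9, 3.0, True, n_frames=60)
        corrected, _, report = sa.dejitter(
            stack, SegmentationConfig(), mode="center_fit"
        )
        centroids = measure_centroids(corrected, SegmentationConfig())
        target = stack.frame_shape[1] // 2
        assert np.nanmax(np.abs(centroids[:, 0] - target)) <= 1.5
        assert report.mode == "center_fit"

    def test_unsegmentable_stack_aborts_with_diagnostic(self):
        frames = np.full((10, 32, 32), 0.5)
        stack = sa.ProjectionStack(
            frames=frames, angles_deg=np.arange(10) * 36.0, pixel_size=1.0
        )
        with pytest.raises(RuntimeError, match="segmentation failed"):
            sa.dejitter(stack, SegmentationConfig())

    def test_output_is_pure_translation_of_input(self, jitter_scene):
        """Each corrected frame cross-correlates perfectly with its source."""
        _, _, stack, _ = jitter_scene(6, 3.0, False, n_frames=100)
        corrected, shifts, _ = sa.dejitter(stack, SegmentationConfig())
        k = int(np.argmax(np.abs(shifts.dx)))
        dx, dy = int(shifts.dx[k]), int(shifts.dy[k])
        rows, cols = stack.frame_shape
        src = stack.frames[k][
            max(-dy, 0) : rows + min(-dy, 0), max(-dx, 0) : cols + min(-dx, 0)
        ]
        dst = corrected.frames[k][
            max(dy, 0) : rows + min(dy, 0), max(dx, 0) : cols + min(dx, 0)
        ]
        np.testing.assert_array_equal(src, dst)
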