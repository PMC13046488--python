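"""The membrane-motion detector: background flattening, running max
projection, difference, spot conversion, and whole-trace properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from elda.motion_viability import (
    motion_difference,
    render_overlay,
    rings_to_spots,
    running_max,
    smooth_trace,
    subtract_background,
    viability_trace,
)
from elda.registration import register_stack
from elda.synth_timelapse import (
    SceneConfig,
    acquisition_for_scene,
    analysis_for_scene,
    simulate_well,
)


def brute_force_running_max(stack: np.ndarray, W: int) -> np.ndarray:
    """Triple-loop oracle for the trailing-window maximum projection."""
    T, H, Wd = stack.shape
    out = np.empty((T - W + 1, H, Wd), dtype=stack.dtype)
    for i in range(T - W + 1):
        for y in range(H):
            for x in range(Wd):
                out[i, y, x] = max(stack[i + k, y, x] for k in range(W))
    return out


class TestSubtractBackground:
    def test_uniform_frame_becomes_zero(self):
        assert subtract_background(np.full((32, 32), 9.0), 6).max() == 0.0

    def test_ramp_removed_discs_retained(self):
        yy, xx = np.mgrid[:64, :64]
        ramp = np.linspace(0, 50, 64)[None, :] * np.ones((64, 1))
        img = ramp.copy()
        centers = [(20, 20), (40, 45)]
        for cy, cx in centers:
            img[np.hypot(yy - cy, xx - cx) < 5] += 60
        out = subtract_background(img, radius=12)
        for cy, cx in centers:
            disc = np.hypot(yy - cy, xx - cx) < 4
            assert out[disc].mean() >= 0.8 * 60
        interior = (yy >= 12) & (yy < 52) & (xx >= 12) & (xx < 52)
        for cy, cx in centers:
            interior &= np.hypot(yy - cy, xx - cx) > 10
        assert out[interior].max() < 0.05 * 50

    def test_near_idempotent_on_background_free_frame(self):
        yy, xx = np.mgrid[:64, :64]
        img = np.zeros((64, 64))
        disc = np.hypot(yy - 30, xx - 30) < 5
        img[disc] = 60.0
        out = subtract_background(img, radius=12)
        assert np.abs(out[disc] - img[disc]).max() <= 0.1 * 60

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((8, 8)), 0)


class TestRunningMax:
    def test_constant_stack_unchanged(self):
        stack = np.full((8, 4, 4), 3.0)
        out = running_max(stack, 6)
        assert out.shape == (3, 4, 4)
        assert np.all(out == 3.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_on_random_stacks(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(3, 11))
        W = int(rng.integers(2, T + 1))
        stack = rng.uniform(0, 100, (T, 4, 4))
        assert np.array_equal(running_max(stack, W), brute_force_running_max(stack, W))

    def test_window_of_one_rejected(self):
        with pytest.raises(ValueError):
            running_max(np.zeros((5, 2, 2)), 1)

    def test_too_short_stack_rejected(self):
        with pytest.raises(ValueError):
            running_max(np.zeros((3, 2, 2)), 6)


class TestMotionDifference:
    def test_static_window_gives_zero(self):
        f = np.random.default_rng(0).uniform(0, 50, (16, 16))
        assert motion_difference(f, f).max() == 0.0

    def test_jittered_disc_leaves_boundary_ring(self):
        yy, xx = np.mgrid[:48, :48]
        disc_a = (np.hypot(yy - 24, xx - 24) < 8).astype(np.float32) * 60
        disc_b = (np.hypot(yy - 24, xx - 25) < 8).astype(np.float32) * 60
        maxproj = np.maximum(disc_a, disc_b)
        diff = motion_difference(maxproj, disc_b)
        ring = (diff > 0)
        expected_ring = (disc_a > 0) & ~(disc_b > 0)
        assert np.array_equal(ring, expected_ring)
        interior = np.hypot(yy - 24, xx - 24.5) < 6
        assert diff[interior].max() == 0.0

    def test_clipped_at_zero(self):
        assert motion_difference(np.zeros((4, 4)), np.ones((4, 4))).min() == 0.0


class TestRingsToSpots:
    def test_zero_image_gives_empty_mask(self):
        assert not rings_to_spots(np.zeros((32, 32)), sigma=5.0).any()

    def test_ideal_ring_fills_to_disc(self):
        yy, xx = np.mgrid[:64, :64]
        rr = np.hypot(yy - 32, xx - 32)
        ring = ((rr >= 9) & (rr <= 11)).astype(np.float32) * 50
        mask = rings_to_spots(ring, sigma=5.0)
        disc = rr <= 10
        assert mask[disc].mean() >= 0.9

    def test_two_separated_jittering_cells_give_two_components(self):
        # two discs, each jittered by one pixel between frames: the
        # difference from the two-frame maximum is a ring fragment per
        # cell, and blurring must leave exactly two spots
        yy, xx = np.mgrid[:96, :96]

        def disc(cy, cx):
            return (np.hypot(yy - cy, xx - cx) < 8).astype(np.float32) * 60

        frame_a = disc(24, 24) + disc(72, 72)
        frame_b = disc(25, 24) + disc(72, 71)
        diff = motion_difference(np.maximum(frame_a, frame_b), frame_b)
        mask = rings_to_spots(diff, sigma=4.0)
        assert ndimage.label(mask)[1] == 2

    def test_bounded_hole_filling(self):
        # a giant ring encloses far more area than one cell; the pocket
        # must not be swallowed when hole size is capped
        yy, xx = np.mgrid[:128, :128]
        rr = np.hypot(yy - 64, xx - 64)
        ring = ((rr >= 40) & (rr <= 44)).astype(np.float32) * 50
        unbounded = rings_to_spots(ring, sigma=2.0)
        bounded = rings_to_spots(ring, sigma=2.0, max_hole_area=400)
        assert unbounded.sum() > bounded.sum()
        assert not bounded[rr < 30].any()


class TestViabilityTrace:
    def test_first_defined_frame_is_motion_window(self, live100_area):
        scene = SceneConfig(n_live=5, n_stroma=0, height=96, width=96, n_frames=10, seed=8)
        stack, _ = simulate_well(scene)
        trace, motion = viability_trace(
            register_stack(stack, analysis_for_scene(scene)),
            acquisition_for_scene(scene),
            analysis_for_scene(scene),
        )
        assert trace.frame_indices[0] == 6
        assert trace.times_min[0] == 180.0
        assert len(trace.raw_area) == 10 - 6

    def test_static_scene_yields_near_zero_area(self, static_area):
        frame_px = 256 * 256
        assert static_area.max() <= 0.01 * frame_px

    def test_live_trace_stable_over_run(self, live100_area):
        m = live100_area.mean()
        assert live100_area.min() >= 0.8 * m
        assert live100_area.max() <= 1.2 * m

    def test_half_dead_scene_gives_half_area(self, live100_area, mixed_5050_area):
        ratio = mixed_5050_area.mean() / live100_area.mean()
        assert abs(ratio - 0.5) <= 0.15 * 0.5

    def test_area_equals_mask_pixel_count(self):
        scene = SceneConfig(n_live=10, n_stroma=0, height=96, width=96, n_frames=10, seed=9)
        stack, _ = simulate_well(scene)
        ana = analysis_for_scene(scene, trace_smooth_frames=1)
        trace, motion = viability_trace(
            register_stack(stack, ana), acquisition_for_scene(scene), ana
        )
        assert np.array_equal(trace.raw_area, motion.masks.sum(axis=(1, 2)))

    def test_intensity_rescaling_leaves_area_unchanged(self):
        scene = SceneConfig(n_live=25, n_stroma=0, height=128, width=128, n_frames=14, seed=12)
        stack, _ = simulate_well(scene)
        ana = analysis_for_scene(scene)
        acq = acquisition_for_scene(scene)
        base = viability_trace(register_stack(stack, ana), acq, ana)[0].raw_area
        for k in (0.5, 2.0, 10.0):
            scaled, _ = simulate_well(scene)
            scaled.frames = scaled.frames * k
            area = viability_trace(register_stack(scaled, ana), acq, ana)[0].raw_area
            assert np.abs(area / base - 1).max() <= 0.05


class TestSmoothTrace:
    def test_window_one_is_identity(self):
        v = np.array([5.0, 1.0, 9.0])
        assert np.array_equal(smooth_trace(v, 1), v)

    def test_median_removes_single_frame_spike(self):
        v = np.array([10.0, 10.0, 100.0, 10.0, 10.0])
        assert np.array_equal(smooth_trace(v, 3), np.full(5, 10.0))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(np.zeros(5), 4)


class TestRenderOverlay:
    def test_empty_mask_is_plain_grayscale(self):
        frame = np.random.default_rng(0).uniform(0, 255, (16, 16))
        out = render_overlay(frame, np.zeros((16, 16), dtype=bool))
        assert out.shape == (16, 16, 3)
        assert np.array_equal(out[..., 0], out[..., 1])

    def test_masked_pixels_tinted_red(self):
        frame = np.full((8, 8), 128.0)
        frame[0, 0] = 0.0  # non-degenerate range
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True
        out = render_overlay(frame, mask)
        assert (out[mask][:, 0] > out[mask][:, 1]).all()

    def test_red_pixels_cover_live_cells(self):
        # demonstration scene with vigorous membrane motion, so each
        # cell's ring closes and fills to a full spot
        scene = SceneConfig(n_live=10, n_stroma=0, height=128, width=128,
                            n_frames=10, jitter_amplitude=1.5, seed=14)
        stack, gt = simulate_well(scene)
        trace, motion = viability_trace(
            register_stack(stack, analysis_for_scene(scene)),
            acquisition_for_scene(scene),
            analysis_for_scene(scene),
        )
        mask = motion.masks[-1]
        yy, xx = np.mgrid[: scene.height, : scene.width]
        covered = []
        for c in gt.tracks[-1][: scene.n_live]:
            cell = np.hypot(yy - c[0], xx - c[1]) < scene.cell_radius
            covered.append(mask[cell].mean())
        assert np.mean(covered) >= 0.8
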