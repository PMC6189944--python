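"""Synthetic scene generator tests: trajectories, rendering, ground truth."""

import math

import numpy as np
import pytest

from servotrack import (
    SceneConfig,
    SceneState,
    StageState,
    TargetShape,
    TrajectoryModel,
    binarize,
    centroid,
    orientation,
    raw_moments,
    render,
    step_scene,
)
from servotrack.scene import sample_noise_circles, target_image_position

DT = 1.0 / 500.0


def make_scene(seed=0, **kwargs):
    kwargs.setdefault("shape", TargetShape.bead(100.0))
    return SceneState.from_seed(seed, **kwargs)


class TestTrajectories:
    def test_zero_speed_is_stationary(self):
        s = make_scene(target_pos=(100.0, 50.0))
        traj = TrajectoryModel(kind="circular", speed_um_s=0.0)
        for _ in range(10):
            step_scene(s, traj, DT)
        np.testing.assert_array_equal(s.target_pos, [100.0, 50.0])

    def test_circular_path_closes(self):
        s = make_scene(target_pos=(1000.0, 0.0), phase=0.0)
        v, d = 5000.0, 2000.0
        traj = TrajectoryModel(kind="circular", speed_um_s=v, diameter_um=d)
        n = int(round(math.pi * d / v / DT))
        start = s.target_pos.copy()
        for _ in range(n):
            step_scene(s, traj, DT)
        np.testing.assert_allclose(s.target_pos, start, atol=15.0)

    def test_run_and_turn_is_deterministic_under_seed(self):
        traj = TrajectoryModel(kind="run_and_turn", speed_um_s=1000.0)
        paths = []
        for _ in range(2):
            s = make_scene(seed=7, target_pos=(0.0, 0.0))
            path = []
            for _ in range(500):
                step_scene(s, traj, DT)
                path.append(s.target_pos.copy())
            paths.append(np.array(path))
        np.testing.assert_array_equal(paths[0], paths[1])

    def test_run_and_turn_confined_to_workspace(self):
        traj = TrajectoryModel(
            kind="run_and_turn", speed_um_s=2000.0, workspace_half_um=500.0,
            turn_rate_hz=0.0, burst_rate_hz=0.0,
        )
        s = make_scene(seed=3, target_pos=(450.0, 0.0), heading=0.1)
        for _ in range(2000):
            step_scene(s, traj, DT)
            assert np.all(np.abs(s.target_pos) <= 500.0 + 1e-9)

    def test_stage_driven_follows_path(self):
        traj = TrajectoryModel(
            kind="stage_driven", path_fn=lambda t: (100.0 * t, -50.0 * t)
        )
        s = make_scene(target_pos=(0.0, 0.0))
        for _ in range(100):
            step_scene(s, traj, DT)
        np.testing.assert_allclose(s.target_pos, [100.0 * s.t, -50.0 * s.t])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryModel(kind="brownian")


class TestRender:
    def test_round_trip_centroid_within_half_pixel(self, optics, rng):
        """Rendered target's measured COG matches the projected truth to
        sub-pixel accuracy over 500 random placements."""
        stage = StageState(rng=np.random.default_rng(0))
        cfg = SceneConfig(chip_edge=False)
        worst = 0.0
        for _ in range(500):
            ratio = rng.choice([140.0, 420.0, 840.0])
            pitch = optics.pixel_pitch(ratio)
            s = make_scene(
                target_pos=rng.uniform(-40, 40, 2) * pitch,
                shape=TargetShape.bead(100.0),
            )
            frame = render(s, stage, optics, ratio, cfg)
            m = raw_moments(binarize(frame))
            xg, yg = centroid(m)
            want = target_image_position(s.target_pos, stage, pitch, 256)
            worst = max(worst, abs(xg - want[0]), abs(yg - want[1]))
        assert worst <= 0.5

    @pytest.mark.parametrize("alpha_deg", [0, 30, 60, 120, 160])
    def test_round_trip_orientation_within_3_degrees(self, optics, alpha_deg):
        alpha = math.radians(alpha_deg)
        s = make_scene(
            target_pos=(0.0, 0.0), heading=alpha, shape=TargetShape.paramecium()
        )
        frame = render(s, StageState(), optics, 840.0, SceneConfig(chip_edge=False))
        phi = orientation(raw_moments(binarize(frame)))
        diff = abs(math.remainder(phi - alpha, math.pi))
        assert math.degrees(diff) < 3.0

    def test_target_outside_fov_leaves_background_only(self, optics):
        s = make_scene(target_pos=(50_000.0 // 4, 0.0))  # far outside 1408 um FOV
        frame = render(s, StageState(), optics, 140.0, SceneConfig(chip_edge=False))
        assert binarize(frame).sum() == 0

    def test_noise_never_touches_target(self, optics):
        cfg = SceneConfig(chip_edge=False, noise_count=15)
        for seed in range(5):
            s = make_scene(seed=seed, target_pos=(0.0, 0.0))
            frame = render(s, StageState(), optics, 140.0, cfg)
            mask = binarize(frame)
            # target pixels form a disk at centre; check a 1-px dilation ring
            pitch = optics.pixel_pitch(140.0)
            r_t = 50.0 / pitch
            ys, xs = np.nonzero(mask)
            d = np.hypot(xs - 127.5, ys - 127.5)
            ring = (d > r_t + 0.6) & (d < r_t + 1.5)
            assert not ring.any()

    def test_noise_resampled_every_frame_and_seeded(self, optics):
        cfg = SceneConfig(chip_edge=False, noise_count=5)
        frames = {}
        for run in range(2):
            s = make_scene(seed=11, target_pos=(0.0, 0.0))
            stage = StageState()
            a = render(s, stage, optics, 140.0, cfg)
            step_scene(s, TrajectoryModel(kind="static"), DT)
            b = render(s, stage, optics, 140.0, cfg)
            frames[run] = (a.pixels, b.pixels)
            assert not np.array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(frames[0][0], frames[1][0])
        np.testing.assert_array_equal(frames[0][1], frames[1][1])

    def test_illumination_drift_moves_background(self, optics):
        cfg = SceneConfig(chip_edge=False, illumination_drift_amplitude=30.0,
                          illumination_drift_period_s=1.0)
        s = make_scene(target_pos=(0.0, 0.0))
        s.t = 0.25  # sin peak
        frame = render(s, StageState(), optics, 140.0, cfg)
        assert frame.pixels[0, 0] == 230
        # the dark target is still segmented despite the drift
        assert binarize(frame).sum() > 100

    def test_chip_edge_appears_dark(self, optics):
        cfg = SceneConfig(chip_edge=True, workspace_half_um=15000.0)
        s = make_scene(target_pos=(14_900.0, 0.0))
        stage = StageState(pos=np.array([-14_900.0, 0.0]))  # FOV at the wall
        frame = render(s, stage, optics, 140.0, cfg)
        # right-hand side of the FOV is beyond the wall -> dark half-plane
        assert (frame.pixels[:, -1] == 20).all()
        assert (frame.pixels[:, 0] != 20).all()

    def test_tool_rendered_with_physical_width(self, optics):
        from servotrack import Microtool

        s = make_scene(target_pos=(99_000.0, 0.0))  # target far outside FOV
        s.tool = Microtool(tip_um=(200.0, 0.0), side="right", width_um=50.0)
        frame = render(s, StageState(), optics, 140.0, SceneConfig(chip_edge=False))
        pitch = optics.pixel_pitch(140.0)
        tip_col = int(round(127.5 + 200.0 / pitch))
        dark_rows = np.nonzero(frame.pixels[:, tip_col + 2] == 20)[0]
        assert len(dark_rows) == pytest.approx(50.0 / pitch, abs=2)
        # nothing to the left of the tip
        assert (frame.pixels[:, : tip_col - 2] != 20).all()


class TestNoiseSampling:
    def test_exclusion_radius_enforced(self, optics):
        cfg = SceneConfig(noise_count=10, noise_exclusion_px=30.0)
        s = make_scene(seed=5)
        for _ in range(50):
            circles = sample_noise_circles(s, cfg, np.array([128.0, 128.0]), 9.1)
            assert len(circles) == 10
            for cx, cy, r in circles:
                assert math.hypot(cx - 128, cy - 128) >= r + 30.0
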