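"""Tracking state machine and closed-loop behavior tests."""

import numpy as np
import pytest

from servotrack import (
    Frame,
    Mode,
    SceneConfig,
    SceneState,
    Simulator,
    TargetShape,
    Tracker,
    TrackerConfig,
    TrajectoryModel,
)
from servotrack.experiments import _bead_tracking_sim

DT = 1.0 / 500.0


def blank_frame(level=200, t=0.0, idx=0):
    return Frame(
        pixels=np.full((256, 256), level, dtype=np.uint8),
        t=t, pixel_pitch=5.5, frame_index=idx, magnification=140.0,
    )


def frame_with_blob(cx, cy, r=9, level=20, t=0.0, idx=0):
    px = np.full((256, 256), 200, dtype=np.uint8)
    ys, xs = np.mgrid[0:256, 0:256]
    px[(xs - cx) ** 2 + (ys - cy) ** 2 <= r * r] = level
    return Frame(
        pixels=px, t=t, pixel_pitch=5.5, frame_index=idx, magnification=140.0
    )


class TestModeMachine:
    def test_search_holds_until_detection_threshold(self):
        tr = Tracker(TrackerConfig(acquire_area_px=50))
        res = tr.update(blank_frame(), stage_pos=np.zeros(2))
        assert res.mode is Mode.SEARCH and res.state is None
        # a 4-px speck is below the detection threshold
        res = tr.update(frame_with_blob(128, 128, r=1, idx=1), stage_pos=np.zeros(2))
        assert res.mode is Mode.SEARCH
        res = tr.update(frame_with_blob(128, 128, r=9, idx=2), stage_pos=np.zeros(2))
        assert res.mode is Mode.TRACK
        assert res.state.area >= 50

    def test_no_track_before_detection(self):
        tr = Tracker(TrackerConfig())
        for i in range(5):
            tr.update(blank_frame(idx=i), stage_pos=np.zeros(2))
        df = tr.record.to_frame()
        assert (df["mode"] == "SEARCH").all()

    def test_lost_after_patience_then_reacquire(self):
        cfg = TrackerConfig(start_mode=Mode.TRACK, lost_patience=5,
                            roi_engage=True, roi_warmup_frames=1)
        tr = Tracker(cfg)
        tr.update(frame_with_blob(100, 100), stage_pos=None)
        assert tr.mode is Mode.TRACK
        for i in range(5):
            res = tr.update(blank_frame(idx=i + 1))
        assert tr.mode is Mode.LOST
        # re-detection requires the full acquire threshold again
        res = tr.update(frame_with_blob(60, 60, idx=7))
        assert res.mode is Mode.TRACK
        assert tr.stable_count == 1  # fresh lock-on, warmup restarted

    def test_empty_frames_below_patience_hold_track(self):
        cfg = TrackerConfig(start_mode=Mode.TRACK, lost_patience=10,
                            roi_engage=True, roi_warmup_frames=1)
        tr = Tracker(cfg)
        tr.update(frame_with_blob(100, 100))
        for i in range(9):
            res = tr.update(blank_frame(idx=i + 1))
            assert res.mode is Mode.TRACK
            assert np.all(res.command_um_s == 0)  # hold while unseen

    def test_roi_engages_only_after_warmup(self):
        cfg = TrackerConfig(start_mode=Mode.TRACK, roi_warmup_frames=3)
        tr = Tracker(cfg)
        for i in range(3):
            tr.update(frame_with_blob(128, 128, idx=i))
            assert tr.current_roi() is None if i < 2 else True
        tr.update(frame_with_blob(128, 128, idx=3))
        assert tr.current_roi() is not None

    def test_roi_follows_previous_state(self):
        cfg = TrackerConfig(start_mode=Mode.TRACK, roi_warmup_frames=1,
                            roi_a=20, roi_b=20)
        tr = Tracker(cfg)
        tr.update(frame_with_blob(100, 90))
        roi = tr.current_roi()
        assert (roi.cx, roi.cy) == pytest.approx((100, 90), abs=0.1)
        tr.update(frame_with_blob(104, 92, idx=1))
        roi = tr.current_roi()
        assert (roi.cx, roi.cy) == pytest.approx((104, 92), abs=0.1)


class TestClosedLoop:
    def test_stationary_target_centered_within_50_frames(self):
        sim = _bead_tracking_sim(1, 140.0, 0.0, True)
        # start with the target well off-centre
        sim.stage.pos = sim.stage.pos + np.array([300.0, -200.0])
        sim.run(50)
        last = sim.truth.to_frame().iloc[-1]
        assert last["tracking_error_um"] < 5.5  # within one pixel at 140x
        assert sim.tracker.mode is Mode.TRACK

    def test_roi_on_off_traces_agree_in_noiseless_scene(self):
        """With no noise the ROI restriction must not change the measured
        COG beyond sub-pixel rendering effects."""
        logs = {}
        for roi_engage in (False, True):
            sim = _bead_tracking_sim(5, 140.0, 2000.0, roi_engage)
            sim.run(600)
            df = sim.tracker.record.to_frame()
            logs[roi_engage] = df[["xg", "yg"]].to_numpy()
        diff = np.abs(logs[True] - logs[False]).max()
        assert diff <= 0.5

    def test_velocity_monotonicity_of_mean_error(self):
        means = []
        for v in (1000.0, 5000.0, 10000.0):
            sim = _bead_tracking_sim(9, 140.0, v, True)
            sim.run(800)
            tr = sim.truth.to_frame()
            means.append(tr["tracking_error_um"].iloc[300:].mean())
        assert means[0] < means[1] < means[2]

    def test_loss_beyond_capability(self):
        """A target far faster than the servo's capture range is lost."""
        cfg = TrackerConfig(start_mode=Mode.TRACK, roi_engage=True,
                            roi_warmup_frames=5, lost_patience=25)
        scene = SceneState.from_seed(0, target_pos=(1000.0, 0.0),
                                     shape=TargetShape.bead(100.0))
        # 120 mm/s: per-frame displacement 240 um = 44 px at 140x
        traj = TrajectoryModel(kind="circular", speed_um_s=120_000.0,
                               diameter_um=8000.0)
        sim = Simulator(scene, traj, SceneConfig(chip_edge=False),
                        Tracker(cfg), ratio=140.0)
        sim.center_on_target()
        sim.run(2000, stop_when=lambda s, r: s.tracker.mode is Mode.LOST
                or s.target_out_of_fov())
        assert sim.tracker.mode is Mode.LOST or sim.target_out_of_fov()


class TestZoom:
    def test_zoom_identity_when_ratios_equal(self):
        a = _bead_tracking_sim(3, 140.0, 1000.0, True)
        b = _bead_tracking_sim(3, 140.0, 1000.0, True)
        b.zoom(140.0, duration_s=1.0)
        a.run(300)
        b.run(300)
        np.testing.assert_array_equal(
            a.tracker.record.to_frame()[["xg", "yg"]].to_numpy(),
            b.tracker.record.to_frame()[["xg", "yg"]].to_numpy(),
        )

    def test_zoom_140_to_840_keeps_lock_on_slow_target(self):
        sim = _bead_tracking_sim(4, 140.0, 1000.0, True)
        sim.run(200)  # settle
        sim.zoom(840.0, duration_s=1.0)
        sim.run(600)  # through the ramp and beyond
        df = sim.tracker.record.to_frame()
        assert not (df["mode"] == "LOST").any()
        assert sim.ratio == 840.0
        # pitch at the end of the ramp is exactly the calibrated value
        assert df["ratio"].iloc[-1] == 840.0
        assert sim.truth.to_frame()["in_fov"].all()

    def test_pitch_rescales_error_continuously(self):
        sim = _bead_tracking_sim(6, 140.0, 1000.0, False)
        sim.run(100)
        sim.zoom(840.0, duration_s=0.5)
        sim.run(300)
        tr = sim.truth.to_frame()
        # no error transient larger than the pre-zoom steady error + margin
        pre = tr["tracking_error_um"].iloc[50:100].mean()
        post = tr["tracking_error_um"].iloc[350:].mean()
        assert post == pytest.approx(pre, abs=3.0)


class TestRecord:
    def test_summary_counts_loss_events(self):
        cfg = TrackerConfig(start_mode=Mode.TRACK, lost_patience=2,
                            roi_engage=True, roi_warmup_frames=1)
        tr = Tracker(cfg)
        tr.update(frame_with_blob(100, 100))
        tr.update(blank_frame(idx=1))
        tr.update(blank_frame(idx=2))  # -> LOST
        tr.update(frame_with_blob(100, 100, idx=3))  # reacquire
        s = tr.record.summary()
        assert s["loss_events"] == 1
        assert s["frames"] == 4

    def test_csv_round_trip(self, tmp_path):
        tr = Tracker(TrackerConfig(start_mode=Mode.TRACK))
        tr.update(frame_with_blob(120, 130))
        path = tmp_path / "log.csv"
        tr.record.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == tr.record.COLUMNS
        assert df["mode"].iloc[0] == "TRACK"
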