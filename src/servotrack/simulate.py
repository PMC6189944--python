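"""Closed-loop simulator: scene -> sensor -> tracker -> stage, per frame.

One :meth:`Simulator.step` renders the frame the sensor would capture,
runs the tracker on it, applies the (latency-delayed) velocity command to
the virtual stage, and advances the world.  Ground truth is logged every
frame alongside the tracker's own record, so experiments can measure the
true tracking error and detect loss of the target from the FOV.

Magnification changes are scheduled with :meth:`Simulator.zoom`: the ratio
ramps linearly over the requested duration and the pixel pitch is
re-evaluated every frame, so the image-to-world error conversion stays
continuous while zooming.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd

from .magnification import MagnificationModel, MagnificationRamp
from .scene import SceneConfig, SceneState, TrajectoryModel, render, step_scene, \
    target_image_position
from .stage import StageState, step_stage
from .tracker import Mode, StepResult, Tracker

__all__ = ["Simulator", "GroundTruthLog"]


class GroundTruthLog:
    """Per-frame world-state log (the simulator's side of the record)."""

    COLUMNS = [
        "frame_index", "t", "true_x_um", "true_y_um", "heading_rad",
        "fov_cx_um", "fov_cy_um", "tracking_error_um",
        "target_img_x", "target_img_y", "in_fov",
        "sensed_x_um", "sensed_y_um", "cmd_vx", "cmd_vy", "ratio",
    ]

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class Simulator:
    """Ties a scene, a virtual stage, the optics model and a tracker together.

    Parameters
    ----------
    scene_state, trajectory, scene_config : scene description
    tracker : Tracker
    stage : StageState, optional
    optics : MagnificationModel, optional
    ratio : float, optional
        Initial magnification ratio; defaults to the tracker's search or
        track ratio depending on its start mode.
    dt : float
        Frame interval (default 1/500 s).
    """

    def __init__(
        self,
        scene_state: SceneState,
        trajectory: TrajectoryModel,
        scene_config: SceneConfig | None = None,
        tracker: Tracker | None = None,
        stage: StageState | None = None,
        optics: MagnificationModel | None = None,
        ratio: float | None = None,
        dt: float = 1.0 / 500.0,
    ) -> None:
        self.scene = scene_state
        self.trajectory = trajectory
        self.scene_config = scene_config or SceneConfig()
        self.tracker = tracker or Tracker()
        self.stage = stage or StageState()
        self.optics = optics or MagnificationModel(
            sensor_pixels=self.scene_config.sensor_pixels
        )
        self.dt = dt
        self.tracker.gains.check_stability(dt)
        if ratio is None:
            ratio = (
                self.tracker.config.search_ratio
                if self.tracker.mode is Mode.SEARCH
                else self.tracker.config.track_ratio
            )
        self.ratio = float(ratio)
        self._ramp: MagnificationRamp | None = None
        self.frame_index = 0
        # actuation latency: commands queue up for latency_frames intervals
        lat = self.tracker.gains.latency_frames
        self._cmd_queue: deque[np.ndarray] = deque([np.zeros(2)] * lat)
        self.truth = GroundTruthLog()

    # -- magnification -------------------------------------------------------

    def zoom(self, to_ratio: float, duration_s: float = 1.0) -> None:
        """Schedule a seamless magnification ramp starting now."""
        lo, hi = self.optics.ratio_range
        if not (lo <= to_ratio <= hi):
            raise ValueError("zoom target outside calibrated range")
        self._ramp = MagnificationRamp(
            from_ratio=self.ratio, to_ratio=to_ratio,
            t0=self.scene.t, duration_s=duration_s,
        )

    def _current_ratio(self) -> float:
        if self._ramp is not None:
            self.ratio = self._ramp.ratio(self.scene.t)
            if self.scene.t >= self._ramp.t0 + self._ramp.duration_s:
                self.ratio = self._ramp.to_ratio
                self._ramp = None
        return self.ratio

    # -- main loop -----------------------------------------------------------

    def step(self) -> StepResult:
        """Advance the closed loop by one frame interval."""
        ratio = self._current_ratio()
        frame = render(
            self.scene, self.stage, self.optics, ratio,
            self.scene_config, frame_index=self.frame_index,
        )
        sensed = self.stage.sensed_pos()
        result = self.tracker.update(frame, stage_pos=sensed, dt=self.dt)

        if self.tracker.gains.latency_frames > 0:
            applied = self._cmd_queue.popleft()
            self._cmd_queue.append(np.asarray(result.command_um_s, dtype=float))
        else:
            applied = np.asarray(result.command_um_s, dtype=float)

        # ground truth is logged at the capture instant, before actuation
        pitch = frame.pixel_pitch
        n = self.scene_config.sensor_pixels
        img_pos = target_image_position(self.scene.target_pos, self.stage, pitch, n)
        fov_c = self.stage.fov_center
        err = self.scene.target_pos - fov_c
        margin = self.scene.shape.max_extent_um / pitch
        in_fov = bool(
            -margin <= img_pos[0] <= n - 1 + margin
            and -margin <= img_pos[1] <= n - 1 + margin
        )
        self.truth.rows.append({
            "frame_index": self.frame_index,
            "t": self.scene.t,
            "true_x_um": self.scene.target_pos[0],
            "true_y_um": self.scene.target_pos[1],
            "heading_rad": self.scene.heading,
            "fov_cx_um": fov_c[0],
            "fov_cy_um": fov_c[1],
            "tracking_error_um": float(np.hypot(*err)),
            "target_img_x": img_pos[0],
            "target_img_y": img_pos[1],
            "in_fov": in_fov,
            "sensed_x_um": sensed[0],
            "sensed_y_um": sensed[1],
            "cmd_vx": applied[0],
            "cmd_vy": applied[1],
            "ratio": ratio,
        })

        step_stage(self.stage, applied, self.dt)
        step_scene(self.scene, self.trajectory, self.dt)
        self.frame_index += 1
        return result

    def run(self, n_frames: int, stop_when=None) -> int:
        """Run up to ``n_frames`` steps; ``stop_when(sim, result)`` can end
        the run early.  Returns the number of frames executed."""
        for i in range(n_frames):
            result = self.step()
            if stop_when is not None and stop_when(self, result):
                return i + 1
        return n_frames

    # -- convenience ---------------------------------------------------------

    def center_on_target(self) -> None:
        """Place the stage so the target sits at the FOV centre (lock-on)."""
        self.stage.pos = -np.asarray(self.scene.target_pos, dtype=float).copy()

    def target_out_of_fov(self) -> bool:
        if not self.truth.rows:
            return False
        return not self.truth.rows[-1]["in_fov"]
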