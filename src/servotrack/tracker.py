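"""Four-step tracking state machine and per-frame measurement pipeline.

The tracker runs one of three modes per frame:

SEARCH
    The stage sweeps a Lissajous path at low magnification; every frame is
    binarized over the full FOV and detection fires when the foreground
    pixel count reaches ``acquire_area_px``.
TRACK
    The frame is binarized, optionally restricted to the elliptical ROI
    propagated from the previous frame's COG and posture, measured for
    COG/posture, and a velocity command toward the FOV centre is emitted.
    The ROI engages only after a configurable number of stable TRACK frames
    so the first lock-on happens on the full FOV.  When the ROI comes up
    empty for ``lost_patience`` consecutive frames the target is declared
    lost.
LOST
    Full-FOV re-detection at the current magnification (an extension for
    unattended runs); a fresh detection returns to TRACK.

When the ROI is engaged, the adaptive threshold is computed from the pixels
inside the ellipse only: noise outside the ROI then has strictly zero
influence on the measurement — the property the ROI exists to provide —
and the processed pixel count drops with the ROI area.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import imaging
from .imaging import Frame, TargetState
from .roi import EllipseROI, roi_from_state
from .stage import (
    ServoGains,
    lissajous_base_freq,
    lissajous_position,
    servo_command,
)

__all__ = ["Mode", "TrackerConfig", "Tracker", "TrackRecord"]


class Mode(enum.Enum):
    SEARCH = "SEARCH"
    TRACK = "TRACK"
    LOST = "LOST"


@dataclass
class TrackerConfig:
    """Tunable tracker parameters (pixel units unless noted)."""

    acquire_area_px: int = 50  # detection: foreground count threshold
    roi_a: float = 20.0
    roi_b: float = 20.0
    roi_engage: bool = True  # False reproduces full-FOV ("typical") processing
    roi_warmup_frames: int = 100  # stable TRACK frames before the ROI engages
    lost_patience: int = 25  # consecutive empty frames before LOST
    search_ratio: float = 140.0
    track_ratio: float = 840.0
    threshold_method: str = "adaptive"
    fixed_level: float | None = None
    #: minimum intensity range inside the ROI for the adaptive threshold to
    #: be re-estimated; below it (ROI fully inside the target, or empty
    #: background) the last valid threshold is held, relying on the small
    #: frame-to-frame change at high frame rates.
    min_contrast: int = 50
    # search path (um / Hz); base_freq None derives from search_speed_um_s
    search_amplitude_um: float = 5000.0
    search_freq_ratio: tuple[int, int] = (3, 2)
    search_speed_um_s: float = 20_000.0
    search_base_freq: float | None = None
    start_mode: Mode = Mode.SEARCH

    def __post_init__(self) -> None:
        if self.acquire_area_px <= 0:
            raise ValueError("acquire_area_px must be positive")
        if self.lost_patience < 1:
            raise ValueError("lost_patience must be >= 1")
        if isinstance(self.start_mode, str):
            self.start_mode = Mode(self.start_mode)

    def base_freq(self) -> float:
        if self.search_base_freq is not None:
            return self.search_base_freq
        return lissajous_base_freq(
            self.search_amplitude_um, self.search_speed_um_s, self.search_freq_ratio
        )


@dataclass
class StepResult:
    """Outcome of one tracker update."""

    state: TargetState | None
    command_um_s: np.ndarray
    mode: Mode
    roi: EllipseROI | None = None
    error_um: np.ndarray | None = None


class TrackRecord:
    """Per-frame log; one row per processed frame."""

    COLUMNS = [
        "frame_index", "t", "mode", "xg", "yg", "phi", "area",
        "error_x_um", "error_y_um", "error_um",
        "roi_cx", "roi_cy", "roi_a", "roi_b", "roi_angle_deg",
        "ratio", "cmd_vx", "cmd_vy",
    ]

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def append(self, frame: Frame, result: StepResult) -> None:
        row = {
            "frame_index": frame.frame_index,
            "t": frame.t,
            "mode": result.mode.value,
            "xg": np.nan, "yg": np.nan, "phi": np.nan, "area": 0,
            "error_x_um": np.nan, "error_y_um": np.nan, "error_um": np.nan,
            "roi_cx": np.nan, "roi_cy": np.nan, "roi_a": np.nan,
            "roi_b": np.nan, "roi_angle_deg": np.nan,
            "ratio": frame.magnification,
            "cmd_vx": result.command_um_s[0],
            "cmd_vy": result.command_um_s[1],
        }
        if result.state is not None:
            row.update(
                xg=result.state.xg, yg=result.state.yg,
                phi=result.state.phi, area=result.state.area,
            )
        if result.error_um is not None:
            row.update(
                error_x_um=result.error_um[0],
                error_y_um=result.error_um[1],
                error_um=float(np.hypot(*result.error_um)),
            )
        if result.roi is not None:
            cx, cy, a, b, deg = result.roi.as_log_row()
            row.update(roi_cx=cx, roi_cy=cy, roi_a=a, roi_b=b, roi_angle_deg=deg)
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        df = self.to_frame()
        track = df[df["mode"] == Mode.TRACK.value]
        err = track["error_um"].dropna()
        return {
            "frames": int(len(df)),
            "duration_s": float(df["t"].iloc[-1] - df["t"].iloc[0]) if len(df) else 0.0,
            "track_frames": int(len(track)),
            "mean_error_um": float(err.mean()) if len(err) else math.nan,
            "sd_error_um": float(err.std(ddof=1)) if len(err) > 1 else math.nan,
            "loss_events": int(
                ((df["mode"] == Mode.LOST.value)
                 & (df["mode"].shift(fill_value="") != Mode.LOST.value)).sum()
            ),
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


class Tracker:
    """Per-frame orchestration of segmentation, ROI, measurement and servo."""

    def __init__(self, config: TrackerConfig | None = None,
                 gains: ServoGains | None = None,
                 max_speed_um_s: float = 1.5e6) -> None:
        self.config = config or TrackerConfig()
        self.gains = gains or ServoGains()
        self.max_speed = max_speed_um_s
        self.mode = self.config.start_mode
        self.prev_state: TargetState | None = None
        self.lost_count = 0
        self.stable_count = 0
        self.held_threshold: float | None = None
        self.record = TrackRecord()

    # -- internals -----------------------------------------------------------

    @property
    def roi_active(self) -> bool:
        return (
            self.config.roi_engage
            and self.prev_state is not None
            and self.stable_count >= self.config.roi_warmup_frames
        )

    def current_roi(self) -> EllipseROI | None:
        if not self.roi_active:
            return None
        return roi_from_state(self.prev_state, self.config.roi_a, self.config.roi_b)

    def _measure_full(self, frame: Frame) -> TargetState | None:
        px = frame.pixels
        if self.config.threshold_method == "adaptive" and px.min() != px.max():
            self.held_threshold = imaging.otsu_threshold(px)
        mask = imaging.binarize(
            frame, self.config.threshold_method, self.config.fixed_level
        )
        return imaging.measure(mask, frame_index=frame.frame_index)

    def _measure_roi(self, frame: Frame, roi: EllipseROI) -> TargetState | None:
        """Measure inside the ROI; the adaptive threshold sees only ROI pixels.

        The threshold is re-estimated from the ROI's own intensity sample
        when that sample spans both classes (contrast >= ``min_contrast``);
        a low-contrast sample (ROI fully inside the dark target, or empty
        background) reuses the last valid threshold instead, so the
        measurement degrades gracefully rather than dropping out.
        """
        (y0, y1, x0, x1), inside = roi.interior_index(frame.shape)
        if not inside.size or not inside.any():
            return None
        sub = frame.pixels[y0:y1, x0:x1]
        vals = sub[inside]
        if self.config.threshold_method == "fixed":
            level = self.config.fixed_level
            if level is None:
                raise ValueError("fixed method requires fixed_level")
            fg = sub < level
        else:
            if int(vals.max()) - int(vals.min()) >= self.config.min_contrast:
                self.held_threshold = imaging.otsu_threshold(vals)
            if self.held_threshold is None:
                return None
            fg = sub <= self.held_threshold
        sub_mask = fg & inside
        m = imaging.raw_moments(sub_mask)
        if m.is_empty:
            return None
        # shift moments back to full-frame coordinates
        xg = m.m10 / m.m00 + x0
        yg = m.m01 / m.m00 + y0
        return TargetState(
            xg=xg, yg=yg, phi=imaging.orientation(m),
            area=int(m.m00), frame_index=frame.frame_index,
        )

    def _servo(self, frame: Frame, state: TargetState) -> tuple[np.ndarray, np.ndarray]:
        cx, cy = frame.center
        error_um = np.array([state.xg - cx, state.yg - cy]) * frame.pixel_pitch
        return error_um, servo_command(error_um, self.gains, self.max_speed)

    def _search_command(self, t: float, dt: float, stage_pos: np.ndarray) -> np.ndarray:
        """Velocity that makes the FOV centre follow the Lissajous path."""
        cfg = self.config
        desired_center = lissajous_position(
            t + dt, cfg.search_amplitude_um, cfg.search_freq_ratio, cfg.base_freq()
        )
        # fov_center = -stage_pos, so the stage target is -desired_center
        v = (-desired_center - np.asarray(stage_pos, dtype=float)) / dt
        return np.clip(v, -self.max_speed, self.max_speed)

    # -- public --------------------------------------------------------------

    def update(self, frame: Frame, stage_pos=None, dt: float = 1.0 / 500.0) -> StepResult:
        """Process one frame and emit the stage velocity command.

        ``stage_pos`` (sensed stage position, um) is needed only in SEARCH
        mode for path following.  Never raises on a valid frame: an empty
        measurement increments the lost counter instead.
        """
        if self.mode is Mode.SEARCH:
            result = self._update_search(frame, stage_pos, dt)
        elif self.mode is Mode.TRACK:
            result = self._update_track(frame)
        else:
            result = self._update_lost(frame)
        self.record.append(frame, result)
        return result

    def _update_search(self, frame: Frame, stage_pos, dt: float) -> StepResult:
        state = self._measure_full(frame)
        if state is not None and state.area >= self.config.acquire_area_px:
            self.mode = Mode.TRACK
            self.prev_state = state
            self.stable_count = 1
            error_um, cmd = self._servo(frame, state)
            return StepResult(state, cmd, Mode.TRACK, error_um=error_um)
        if stage_pos is None:
            cmd = np.zeros(2)
        else:
            cmd = self._search_command(frame.t, dt, stage_pos)
        return StepResult(None, cmd, Mode.SEARCH)

    def _update_track(self, frame: Frame) -> StepResult:
        roi = self.current_roi()
        if roi is not None:
            state = self._measure_roi(frame, roi)
        else:
            state = self._measure_full(frame)
            if state is not None and state.area == 0:
                state = None
        if state is None:
            self.lost_count += 1
            if self.lost_count >= self.config.lost_patience:
                self.mode = Mode.LOST
                self.prev_state = None
                self.stable_count = 0
                self.lost_count = 0
                return StepResult(None, np.zeros(2), Mode.LOST, roi=roi)
            # hold position while the target is momentarily unseen
            return StepResult(None, np.zeros(2), Mode.TRACK, roi=roi)
        self.lost_count = 0
        self.stable_count += 1
        self.prev_state = state
        error_um, cmd = self._servo(frame, state)
        return StepResult(state, cmd, Mode.TRACK, roi=roi, error_um=error_um)

    def _update_lost(self, frame: Frame) -> StepResult:
        state = self._measure_full(frame)
        if state is not None and state.area >= self.config.acquire_area_px:
            self.mode = Mode.TRACK
            self.prev_state = state
            self.stable_count = 1
            error_um, cmd = self._servo(frame, state)
            return StepResult(state, cmd, Mode.TRACK, error_um=error_um)
        return StepResult(None, np.zeros(2), Mode.LOST)
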