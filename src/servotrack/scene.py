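"""Synthetic microscopy scene generator with per-frame ground truth.

Renders what the high-speed sensor would see: a dark target (bead or
elongated swimmer) on a bright background, optionally with randomly
re-sampled circular noise blobs, a global illumination drift, the dark edge
of the microfluidic chip, and an intruding microtool bar.  World
coordinates are um in the chip frame (x rightward, y downward, matching
image axes); the chip-frame point imaged at the FOV centre is ``-stage.pos``
(see :mod:`servotrack.stage`).

The target is rendered with area-coverage anti-aliasing (supersampling) so
that sub-pixel motion is visible to the centroid and measurement accuracy
is not quantised to whole pixels.  Noise circles and the microtool are
rendered with hard edges at the target intensity; noise placement is
rejection-sampled so it never touches the target (and, when configured, an
exclusion zone large enough to keep it out of the tracking ROI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._raster import fill_circles, fill_ellipse_aa
from .imaging import Frame
from .magnification import MagnificationModel
from .stage import StageState

__all__ = [
    "TargetShape",
    "Microtool",
    "TrajectoryModel",
    "SceneConfig",
    "SceneState",
    "step_scene",
    "render",
    "target_image_position",
    "paramecium_trajectory",
]

WORKSPACE_HALF_UM = 15_000.0  # 30 mm x 30 mm chip workspace


@dataclass(frozen=True)
class TargetShape:
    """Elliptical body: half-length and half-width in um (equal for a bead)."""

    half_length_um: float
    half_width_um: float

    def __post_init__(self) -> None:
        if not (self.half_length_um > 0 and self.half_width_um > 0):
            raise ValueError("target shape must be positive")

    @classmethod
    def bead(cls, diameter_um: float = 100.0) -> "TargetShape":
        r = diameter_um / 2.0
        return cls(r, r)

    @classmethod
    def paramecium(cls, length_um: float = 150.0, width_um: float = 35.0) -> "TargetShape":
        return cls(length_um / 2.0, width_um / 2.0)

    @property
    def max_extent_um(self) -> float:
        return max(self.half_length_um, self.half_width_um)


@dataclass
class Microtool:
    """Thin stimulation probe entering the FOV from one side as a dark bar.

    ``tip_um`` is the world position of the probe tip; the bar extends from
    the tip back to the ``side`` of entry with the given width (50 um for
    the probe this emulates).
    """

    tip_um: np.ndarray
    side: str = "right"  # left | right | top | bottom
    width_um: float = 50.0

    def __post_init__(self) -> None:
        self.tip_um = np.asarray(self.tip_um, dtype=float).copy()
        if self.side not in ("left", "right", "top", "bottom"):
            raise ValueError(f"unknown tool side {self.side!r}")
        if not self.width_um > 0:
            raise ValueError("tool width must be positive")


@dataclass
class TrajectoryModel:
    """Target motion law.

    kinds
    -----
    ``static``
        Target does not move.
    ``circular``
        Constant speed around a circle of ``diameter_um`` centred at
        ``center_um`` (the bead-on-a-piezo-stage benchmark).
    ``run_and_turn``
        Constant cruise speed with heading persistence, Poisson-timed
        reorientation events, occasional speed bursts capped at
        ``burst_speed_um_s``, and specular reflection at the chip walls.
        A stand-in for a ciliate swimmer; not biologically calibrated.
    ``stage_driven``
        Position prescribed by ``path_fn(t)``.
    """

    kind: str = "static"
    speed_um_s: float = 1000.0
    diameter_um: float = 2000.0
    center_um: tuple[float, float] = (0.0, 0.0)
    turn_rate_hz: float = 0.5
    burst_rate_hz: float = 0.05
    burst_speed_um_s: float = 2000.0
    burst_duration_s: float = 0.3
    workspace_half_um: float = WORKSPACE_HALF_UM
    path_fn: object = None  # callable t -> (x_um, y_um) for stage_driven

    def __post_init__(self) -> None:
        if self.kind not in ("static", "circular", "run_and_turn", "stage_driven"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.speed_um_s < 0:
            raise ValueError("speed must be >= 0")


@dataclass
class SceneConfig:
    """Rendering parameters (intensities are 8-bit levels)."""

    sensor_pixels: int = 256
    background: float = 200.0
    target_intensity: float = 20.0
    illumination_drift_amplitude: float = 0.0
    illumination_drift_period_s: float = 2.0
    noise_count: int = 0
    #: debris-scale noise: radii up to slightly larger than the 100 um
    #: bead's image at low magnification, so the area-weighted COG degrades
    #: gradually with noise density instead of saturating at one circle
    noise_radius_px: tuple[float, float] = (3.0, 12.0)
    #: extra clearance (px) between a noise circle's rim and the target
    #: centre, beyond the target's own rendered extent; raise it to keep
    #: noise out of the tracking ROI as well.
    noise_exclusion_px: float | None = None
    chip_edge: bool = True
    workspace_half_um: float = WORKSPACE_HALF_UM
    supersample: int = 4


@dataclass
class SceneState:
    """Ground-truth world state of the scene (mutated in place per frame)."""

    target_pos: np.ndarray = field(default_factory=lambda: np.zeros(2))
    heading: float = 0.0
    shape: TargetShape = field(default_factory=TargetShape.bead)
    tool: Microtool | None = None
    beads: np.ndarray | None = None  # (n, 2) static bead field, world um
    bead_radius_um: float = 50.0
    t: float = 0.0
    phase: float = 0.0  # circular-trajectory phase
    burst_until: float = -1.0
    traj_rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )
    noise_rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(1)
    )

    def __post_init__(self) -> None:
        self.target_pos = np.asarray(self.target_pos, dtype=float).copy()
        if self.beads is not None:
            self.beads = np.asarray(self.beads, dtype=float).reshape(-1, 2)

    @classmethod
    def from_seed(cls, seed, **kwargs) -> "SceneState":
        """Build a state with independent trajectory/noise random streams.

        ``seed`` may be an int or a ``numpy.random.SeedSequence``.
        """
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        traj_ss, noise_ss = ss.spawn(2)
        return cls(
            traj_rng=np.random.default_rng(traj_ss),
            noise_rng=np.random.default_rng(noise_ss),
            **kwargs,
        )


def paramecium_trajectory(**overrides) -> TrajectoryModel:
    """Run-and-turn swimmer defaults: 1 mm/s cruise, bursts capped at 2 mm/s."""
    kw = dict(kind="run_and_turn", speed_um_s=1000.0, burst_speed_um_s=2000.0)
    kw.update(overrides)
    return TrajectoryModel(**kw)


def step_scene(state: SceneState, traj: TrajectoryModel, dt: float) -> SceneState:
    """Advance the world one frame interval; reproducible under the seeds.

    Noise circle positions are drawn at render time (they depend on the
    image geometry); this function advances the target and scene clock.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if traj.kind == "static" or traj.speed_um_s == 0 and traj.kind != "stage_driven":
        pass
    elif traj.kind == "circular":
        radius = traj.diameter_um / 2.0
        omega = traj.speed_um_s / radius
        state.phase += omega * dt
        state.target_pos = np.asarray(traj.center_um) + radius * np.array(
            [math.cos(state.phase), math.sin(state.phase)]
        )
        state.heading = state.phase + math.pi / 2.0
    elif traj.kind == "run_and_turn":
        rng = state.traj_rng
        # Poisson-timed events: reorientation and speed burst
        if rng.random() < traj.turn_rate_hz * dt:
            state.heading = rng.uniform(-math.pi, math.pi)
        if traj.burst_rate_hz > 0 and rng.random() < traj.burst_rate_hz * dt:
            state.burst_until = state.t + traj.burst_duration_s
        speed = (
            traj.burst_speed_um_s if state.t < state.burst_until else traj.speed_um_s
        )
        step = speed * dt * np.array(
            [math.cos(state.heading), math.sin(state.heading)]
        )
        pos = state.target_pos + step
        # specular reflection at the chip walls
        half = traj.workspace_half_um
        for axis in (0, 1):
            if pos[axis] > half:
                pos[axis] = 2 * half - pos[axis]
                state.heading = _reflect_heading(state.heading, axis)
            elif pos[axis] < -half:
                pos[axis] = -2 * half - pos[axis]
                state.heading = _reflect_heading(state.heading, axis)
        state.target_pos = pos
    elif traj.kind == "stage_driven":
        if traj.path_fn is None:
            raise ValueError("stage_driven trajectory requires path_fn")
        state.target_pos = np.asarray(traj.path_fn(state.t + dt), dtype=float)
    state.t += dt
    return state


def _reflect_heading(heading: float, axis: int) -> float:
    ca, sa = math.cos(heading), math.sin(heading)
    if axis == 0:
        ca = -ca
    else:
        sa = -sa
    return math.atan2(sa, ca)


def target_image_position(
    target_pos_um, stage: StageState, pixel_pitch: float, sensor_pixels: int = 256
) -> np.ndarray:
    """Project a chip-frame point to pixel coordinates of the current FOV."""
    c_world = -np.asarray(stage.pos, dtype=float)
    center_px = (sensor_pixels - 1) / 2.0
    return (np.asarray(target_pos_um, dtype=float) - c_world) / pixel_pitch + center_px


def sample_noise_circles(
    state: SceneState,
    config: SceneConfig,
    target_px: np.ndarray,
    target_extent_px: float,
) -> list[tuple[float, float, float]]:
    """Fresh per-frame noise circles (cx, cy, r) in pixel coordinates.

    Rejection-sampled so no circle's rim comes within the exclusion radius
    of the target centre; with the default exclusion (target extent + 3 px)
    no noise pixel ever touches a target pixel.
    """
    if config.noise_count <= 0:
        return []
    n = config.sensor_pixels
    rmin, rmax = config.noise_radius_px
    excl = config.noise_exclusion_px
    if excl is None:
        excl = target_extent_px + 3.0
    rng = state.noise_rng
    need = config.noise_count
    circles: list[tuple[float, float, float]] = []
    for _attempt in range(50):
        if need <= 0:
            break
        # batched rejection sampling: draw a surplus, keep valid ones
        m = max(2 * need, 8)
        cxy = rng.uniform(0, n - 1, size=(m, 2))
        rr = rng.uniform(rmin, rmax, size=m)
        d = np.hypot(cxy[:, 0] - target_px[0], cxy[:, 1] - target_px[1])
        ok = np.nonzero(d >= rr + excl)[0][:need]
        circles.extend((cxy[i, 0], cxy[i, 1], rr[i]) for i in ok)
        need = config.noise_count - len(circles)
    return circles


def render(
    state: SceneState,
    stage: StageState,
    optics: MagnificationModel,
    ratio: float,
    config: SceneConfig | None = None,
    frame_index: int = 0,
) -> Frame:
    """Render the sensor frame for the current world and stage state.

    The target appears dark on a bright background at
    ``(target_pos - fov_center) / pixel_pitch`` from the image centre; the
    chip edge shows as a dark half-plane when the FOV overlaps the
    workspace boundary, and the microtool as a dark bar of physical width
    ``tool.width_um``.  Noise circles are re-sampled on every call from the
    scene's noise stream (call once per frame).
    """
    if config is None:
        config = SceneConfig()
    n = config.sensor_pixels
    pitch = optics.pixel_pitch(ratio)
    center_px = (n - 1) / 2.0
    c_world = -stage.pos

    bg = config.background
    if config.illumination_drift_amplitude:
        bg = bg + config.illumination_drift_amplitude * math.sin(
            2.0 * math.pi * state.t / config.illumination_drift_period_s
        )
    bg = min(max(bg, 0.0), 255.0)
    # uint8 canvas; anti-aliased draws blend in float within their bbox only
    img = np.full((n, n), np.uint8(round(bg)), dtype=np.uint8)
    tgt_int = np.uint8(round(config.target_intensity))

    if config.chip_edge or state.tool is not None:
        # world coordinates of pixel rows/columns (for edge and tool)
        xw = c_world[0] + (np.arange(n) - center_px) * pitch
        yw = c_world[1] + (np.arange(n) - center_px) * pitch

    if config.chip_edge:
        half = config.workspace_half_um
        col_out = np.abs(xw) > half
        row_out = np.abs(yw) > half
        if col_out.any():
            img[:, col_out] = tgt_int
        if row_out.any():
            img[row_out, :] = tgt_int

    if state.beads is not None and len(state.beads):
        r_px = state.bead_radius_um / pitch
        for bx, by in state.beads:
            px = (np.array([bx, by]) - c_world) / pitch + center_px
            fill_ellipse_aa(
                img, px[0], px[1], r_px, r_px, 0.0,
                config.target_intensity, config.supersample,
            )

    target_px = target_image_position(state.target_pos, stage, pitch, n)
    ha = state.shape.half_length_um / pitch
    hb = state.shape.half_width_um / pitch
    fill_ellipse_aa(
        img, target_px[0], target_px[1], ha, hb, state.heading,
        config.target_intensity, config.supersample,
    )

    if state.tool is not None:
        _render_tool(img, state.tool, xw, yw, tgt_int)

    target_extent_px = state.shape.max_extent_um / pitch
    circles = sample_noise_circles(state, config, target_px, target_extent_px)
    fill_circles(img, circles, tgt_int)

    return Frame(
        pixels=img,
        t=state.t,
        pixel_pitch=pitch,
        frame_index=frame_index,
        magnification=ratio,
    )


def _render_tool(img, tool: Microtool, xw, yw, intensity):
    half_w = tool.width_um / 2.0
    tx, ty = tool.tip_um
    if tool.side in ("left", "right"):
        rows = np.abs(yw - ty) <= half_w
        cols = xw >= tx if tool.side == "right" else xw <= tx
    else:
        cols = np.abs(xw - tx) <= half_w
        rows = yw >= ty if tool.side == "bottom" else yw <= ty
    if rows.any() and cols.any():
        img[np.ix_(rows, cols)] = intensity
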