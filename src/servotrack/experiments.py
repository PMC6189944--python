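"""Seeded simulation studies: target search, velocity sweep, noise robustness,
and the microtool-intrusion scenario.

Each experiment builds a full closed-loop :class:`~servotrack.simulate.Simulator`
from an :class:`ExperimentSpec`, runs it, and returns a tidy summary table;
per-frame CSV logs can be retained by passing ``out_dir``.  Every result is
reproducible from (spec, seed): the scene trajectory, the per-frame noise
and the stage encoder noise draw from independent streams spawned from the
spec seed, so runs that differ only in noise density share the identical
target trajectory.

Default problem sizes (documented in the methods note): the velocity sweep
uses the calibration extremes plus a mid ratio; the search study uses three
ratios with a 30 s cap; the noise study runs at 140x with the bead circling
at 10 mm/s and a 60 s cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scene import (
    Microtool,
    SceneConfig,
    SceneState,
    TargetShape,
    TrajectoryModel,
)
from .simulate import Simulator
from .stage import StageState, lissajous_position
from .tracker import Mode, Tracker, TrackerConfig

__all__ = [
    "ExperimentSpec",
    "run_search_time",
    "run_velocity_sweep",
    "run_noise_robustness",
    "run_tool_intrusion",
]

DT = 1.0 / 500.0


@dataclass
class ExperimentSpec:
    """Which study to run, how often, and over what grid.

    ``grid`` keys (all optional, with per-experiment defaults):
    ``ratios``, ``velocities_mm_s``, ``noise_counts``.
    """

    which: str = "velocity_sweep"
    repeats: int = 1
    seed: int = 0
    grid: dict = field(default_factory=dict)
    cap_duration_s: float = 60.0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.grid_ok():
            raise ValueError("grids must be non-empty")

    def grid_ok(self) -> bool:
        return all(len(v) > 0 for v in self.grid.values() if v is not None)


def _spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def _bead_tracking_sim(
    seed,
    ratio: float,
    velocity_um_s: float,
    roi_engage: bool,
    noise_count: int = 0,
    noise_exclusion_px: float | None = None,
    roi_a: float = 20.0,
    roi_b: float = 20.0,
) -> Simulator:
    """Closed-loop sim of the bead-on-a-circle benchmark, locked on at t=0."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    scene_ss, stage_ss = ss.spawn(2)
    radius = 1000.0  # 2.0 mm diameter circle
    scene = SceneState.from_seed(
        scene_ss,
        target_pos=(radius, 0.0),
        shape=TargetShape.bead(100.0),
        phase=0.0,
    )
    traj = TrajectoryModel(
        kind="circular", speed_um_s=velocity_um_s, diameter_um=2 * radius,
        center_um=(0.0, 0.0),
    )
    config = SceneConfig(
        noise_count=noise_count, noise_exclusion_px=noise_exclusion_px,
        chip_edge=False,
    )
    tracker = Tracker(
        TrackerConfig(
            roi_a=roi_a, roi_b=roi_b, roi_engage=roi_engage,
            start_mode=Mode.TRACK, track_ratio=ratio,
        )
    )
    stage = StageState(rng=np.random.default_rng(stage_ss))
    sim = Simulator(
        scene, traj, config, tracker, stage=stage, ratio=ratio, dt=DT
    )
    sim.center_on_target()
    return sim


def _failed(sim: Simulator) -> bool:
    return sim.tracker.mode is Mode.LOST or sim.target_out_of_fov()


# ---------------------------------------------------------------------------
# search time vs magnification
# ---------------------------------------------------------------------------

def run_search_time(spec: ExperimentSpec) -> pd.DataFrame:
    """Time to find a bead by Lissajous search, per magnification ratio.

    Per repeat, 20 beads (diameter 100 um) are scattered uniformly in a
    10 mm x 10 mm square; the identical layout is searched at every ratio,
    starting from the same point of the path.  The search ends at the first
    frame whose foreground pixel count reaches the detection threshold;
    runs that exceed the cap are recorded as censored at the cap.

    Returns a table with one row per (ratio, repeat) and per-ratio means.
    """
    ratios = list(spec.grid.get("ratios", (140, 420, 1400)))
    n_beads = int(spec.grid.get("n_beads", 20))
    seeds = _spawn_seeds(spec.seed, spec.repeats)
    cap_frames = int(round(spec.cap_duration_s / DT))
    rows = []
    for rep, rep_ss in enumerate(seeds):
        layout_rng = np.random.default_rng(rep_ss)
        beads = layout_rng.uniform(-5000.0, 5000.0, size=(n_beads, 2))
        for ratio in ratios:
            scene_ss, stage_ss = rep_ss.spawn(2)
            scene = SceneState.from_seed(
                scene_ss,
                target_pos=beads[0],
                shape=TargetShape.bead(100.0),
                beads=beads[1:],
                bead_radius_um=50.0,
            )
            tracker = Tracker(
                TrackerConfig(start_mode=Mode.SEARCH, search_ratio=ratio)
            )
            stage = StageState(rng=np.random.default_rng(stage_ss))
            # start the FOV on the search path
            stage.pos = -lissajous_position(
                0.0, tracker.config.search_amplitude_um,
                tracker.config.search_freq_ratio, tracker.config.base_freq(),
            )
            sim = Simulator(
                scene, TrajectoryModel(kind="static"), SceneConfig(chip_edge=False),
                tracker, stage=stage, ratio=ratio, dt=DT,
            )
            ran = sim.run(
                cap_frames, stop_when=lambda s, r: r.mode is Mode.TRACK
            )
            found = sim.tracker.mode is Mode.TRACK
            t_found = ran * DT if found else spec.cap_duration_s
            rows.append({
                "ratio": ratio, "repeat": rep,
                "search_time_s": t_found, "censored": not found,
            })
            _maybe_log(spec, sim, f"search_r{ratio}_rep{rep}")
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("ratio")["search_time_s"].agg(["mean", "std"]).reset_index()
        .rename(columns={"mean": "mean_s", "std": "sd_s"})
    )
    return df.merge(summary, on="ratio")


# ---------------------------------------------------------------------------
# tracking error vs target velocity
# ---------------------------------------------------------------------------

def run_velocity_sweep(
    spec: ExperimentSpec,
    transient_frames: int = 300,
    measure_frames: int = 1000,
) -> pd.DataFrame:
    """Steady-state tracking error of the circling 100 um bead.

    For each (magnification ratio, velocity, ROI on/off) the loop runs a
    lock-on transient and then 1000 steady-state frames; the reported error
    is the true distance between the target and the FOV centre, in um.
    ``lost`` flags runs where the tracker declared loss or the target left
    the FOV.
    """
    ratios = list(spec.grid.get("ratios", (140, 560, 1400)))
    velocities = list(spec.grid.get("velocities_mm_s", (1, 5, 10, 15)))
    seeds = _spawn_seeds(spec.seed, spec.repeats)
    rows = []
    for rep, rep_ss in enumerate(seeds):
        cond_seeds = rep_ss.spawn(len(ratios) * len(velocities) * 2)
        i = 0
        for roi_engage in (False, True):
            for ratio in ratios:
                for v in velocities:
                    sim = _bead_tracking_sim(
                        cond_seeds[i], ratio, v * 1000.0, roi_engage
                    )
                    i += 1
                    sim.run(transient_frames)
                    sim.run(measure_frames, stop_when=lambda s, r: _failed(s))
                    truth = sim.truth.to_frame().iloc[transient_frames:]
                    err = truth["tracking_error_um"]
                    rows.append({
                        "ratio": ratio,
                        "velocity_mm_s": v,
                        "roi": roi_engage,
                        "repeat": rep,
                        "mean_error_um": float(err.mean()),
                        "sd_error_um": float(err.std(ddof=1)),
                        "n_frames": int(len(err)),
                        "lost": _failed(sim),
                    })
                    _maybe_log(
                        spec, sim,
                        f"velocity_r{ratio}_v{v}_roi{int(roi_engage)}_rep{rep}",
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tracking time vs noise density
# ---------------------------------------------------------------------------

def run_noise_robustness(
    spec: ExperimentSpec,
    velocity_mm_s: float = 10.0,
    ratio: float = 140.0,
    noise_start_s: float = 1.0,
    repeats: int | None = None,
) -> pd.DataFrame:
    """Total tracking time under per-frame random circular noise.

    The bead circles at ``velocity_mm_s`` under 140x; tracking starts in a
    noiseless scene and the noise (1/5/10/15 circles, re-sampled every
    frame, rejection-sampled away from the target and the ROI extent) is
    switched on once tracking is stable.  The run ends when the target
    leaves the FOV or the tracker declares loss, capped at
    ``spec.cap_duration_s``.  Both processing methods (full-FOV and
    ROI-engaged) see identical noise statistics.
    """
    noise_counts = list(spec.grid.get("noise_counts", (1, 5, 10, 15)))
    n_rep = repeats if repeats is not None else spec.repeats
    seeds = _spawn_seeds(spec.seed, n_rep)
    cap_frames = int(round(spec.cap_duration_s / DT))
    warm_frames = int(round(noise_start_s / DT))
    roi_a = 20.0
    exclusion = roi_a + 5.0
    rows = []
    for rep, rep_ss in enumerate(seeds):
        cond_seeds = rep_ss.spawn(len(noise_counts) * 2)
        i = 0
        for roi_engage in (False, True):
            for count in noise_counts:
                sim = _bead_tracking_sim(
                    cond_seeds[i], ratio, velocity_mm_s * 1000.0, roi_engage,
                    noise_count=0, noise_exclusion_px=exclusion,
                )
                i += 1
                sim.run(warm_frames, stop_when=lambda s, r: _failed(s))
                sim.scene_config.noise_count = count
                sim.run(
                    cap_frames - warm_frames, stop_when=lambda s, r: _failed(s)
                )
                failed = _failed(sim)
                t_end = sim.truth.rows[-1]["t"] if failed else spec.cap_duration_s
                rows.append({
                    "noise_count": count,
                    "method": "roi" if roi_engage else "full_fov",
                    "repeat": rep,
                    "tracking_time_s": float(t_end),
                    "failed": bool(failed),
                })
                _maybe_log(
                    spec, sim,
                    f"noise_n{count}_{'roi' if roi_engage else 'full'}_rep{rep}",
                )
    df = pd.DataFrame(rows)
    means = (
        df.groupby(["noise_count", "method"])["tracking_time_s"]
        .mean().rename("mean_tracking_time_s").reset_index()
    )
    return df.merge(means, on=["noise_count", "method"])


# ---------------------------------------------------------------------------
# microtool intrusion
# ---------------------------------------------------------------------------

def run_tool_intrusion(
    seed: int = 0,
    roi_engage: bool = True,
    ratio: float = 840.0,
    approach_speed_um_s: float = 100.0,
    standoff_um: float = 120.0,
    duration_s: float = 1.5,
    with_tool: bool = True,
) -> Simulator:
    """Advance a 50 um microtool toward a tracked elongated swimmer.

    The target sits still at the chip centre under 840x with the elongated
    ROI preset (a=100, b=20 px); the tool enters from the right of the FOV
    (half-width 139.5 um) and its tip approaches the target along the x
    axis, stopping at ``standoff_um`` — inside the FOV but strictly outside
    the ROI ellipse (109 um along the major axis), so the ROI never sees
    it.  Run once with ``with_tool=False`` and the same seed to get the
    disturbance-free reference trace.
    """
    ss = np.random.SeedSequence(seed)
    scene_ss, stage_ss = ss.spawn(2)
    scene = SceneState.from_seed(
        scene_ss,
        target_pos=(0.0, 0.0),
        heading=0.0,
        shape=TargetShape.paramecium(),
    )
    config = SceneConfig(chip_edge=False)
    tracker = Tracker(
        TrackerConfig(
            roi_a=100.0, roi_b=20.0, roi_engage=roi_engage,
            roi_warmup_frames=50, start_mode=Mode.TRACK, track_ratio=ratio,
        )
    )
    stage = StageState(rng=np.random.default_rng(stage_ss))
    sim = Simulator(
        scene, TrajectoryModel(kind="static"), config, tracker,
        stage=stage, ratio=ratio, dt=DT,
    )
    sim.center_on_target()
    n_frames = int(round(duration_s / DT))
    tip_x0 = 200.0  # starts outside the FOV half-width, enters while closing
    for k in range(n_frames):
        if with_tool:
            tip_x = max(tip_x0 - approach_speed_um_s * k * DT, standoff_um)
            scene.tool = Microtool(tip_um=(tip_x, 0.0), side="right", width_um=50.0)
        sim.step()
    return sim


def _maybe_log(spec: ExperimentSpec, sim: Simulator, name: str) -> None:
    if spec.out_dir is None:
        return
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim.tracker.record.to_csv(out / f"{name}_track.csv")
    sim.truth.to_csv(out / f"{name}_truth.csv")
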