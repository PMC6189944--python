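"""Virtual XY stage and the image-error -> stage-velocity servo law.

The stage carries the microfluidic chip under a fixed camera.  Its state is
the chip displacement in um; the chip-frame point imaged at the FOV centre
is therefore ``-pos`` (moving the stage by +s shifts the chip by +s, so the
optical axis lands on chip coordinate -s).

Control is a saturated discrete proportional law: the image-space error
(COG minus FOV centre, converted to um via the pixel pitch) is multiplied
by -kp and clamped per-axis to the drive's maximum speed.  The discrete
loop x_{k+1} = x_k - kp*dt*x_k is stable for kp*dt < 2; with the default
kp = 250 /s at 500 FPS, kp*dt = 0.5.

The drive positions to 0.2 um (200 nm); that accuracy is modelled as
Gaussian noise on the *reported* (encoder) position, the true position
being the deterministic integral of the commanded velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ServoGains",
    "StageState",
    "servo_command",
    "step_stage",
    "lissajous_position",
    "lissajous_base_freq",
]

#: Default frame interval (500 FPS sensor).
DEFAULT_DT = 1.0 / 500.0


@dataclass
class ServoGains:
    """Proportional gain [1/s] on the um image error, plus actuation latency
    in frames (1 frame models the few-ms capture-to-command pipeline)."""

    kp: float = 250.0
    latency_frames: int = 1

    def __post_init__(self) -> None:
        if not self.kp > 0:
            raise ValueError("kp must be positive")
        if self.latency_frames < 0:
            raise ValueError("latency_frames must be >= 0")

    def check_stability(self, dt: float) -> None:
        """Discrete-loop stability guard: requires kp*dt < 2."""
        if not self.kp * dt < 2.0:
            raise ValueError(
                f"unstable discrete loop: kp*dt = {self.kp * dt:.3g} >= 2"
            )


@dataclass
class StageState:
    """XY stage: true position/velocity in um, drive limits, encoder noise."""

    pos: np.ndarray = field(default_factory=lambda: np.zeros(2))
    vel: np.ndarray = field(default_factory=lambda: np.zeros(2))
    max_speed: float = 1.5e6  # um/s (1500 mm/s)
    pos_noise_sd: float = 0.2  # um (200 nm positioning accuracy)
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float).copy()
        self.vel = np.asarray(self.vel, dtype=float).copy()

    @property
    def fov_center(self) -> np.ndarray:
        """Chip-frame coordinate currently imaged at the FOV centre."""
        return -self.pos

    def sensed_pos(self) -> np.ndarray:
        """Encoder reading: true position plus Gaussian positioning noise."""
        return self.pos + self.rng.normal(0.0, self.pos_noise_sd, size=2)


def servo_command(error_um, gains: ServoGains, max_speed: float = 1.5e6) -> np.ndarray:
    """Velocity command [um/s] = -kp * error, clamped per axis.

    ``error_um`` is the target's offset from the FOV centre in chip-frame um,
    i.e. (COG_px - centre_px) * pixel_pitch.
    """
    cmd = -gains.kp * np.asarray(error_um, dtype=float)
    return np.clip(cmd, -max_speed, max_speed)


def step_stage(state: StageState, command, dt: float) -> StageState:
    """Advance the stage one interval under a (clamped) velocity command."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    vel = np.clip(np.asarray(command, dtype=float), -state.max_speed, state.max_speed)
    state.vel = vel
    state.pos = state.pos + vel * dt
    return state


def lissajous_position(
    t: float,
    amplitude_um: float = 5000.0,
    freq_ratio: tuple[int, int] = (3, 2),
    base_freq: float = 0.25,
    delta: float = math.pi / 2,
) -> np.ndarray:
    """Point of the search path at time t:
    ``(A sin(2 pi p f t), A sin(2 pi q f t + delta))``.

    A closed space-covering scan used to sweep the scatter region when no
    target is in view; the default 5 mm amplitude spans a 10 mm x 10 mm
    square.
    """
    p, q = freq_ratio
    w = 2.0 * math.pi * base_freq
    return np.array(
        [
            amplitude_um * math.sin(p * w * t),
            amplitude_um * math.sin(q * w * t + delta),
        ]
    )


def lissajous_base_freq(
    amplitude_um: float,
    path_speed_um_s: float,
    freq_ratio: tuple[int, int] = (3, 2),
) -> float:
    """Base frequency so the RMS speed along the path equals ``path_speed``.

    The RMS magnitude of the path derivative is
    ``A * 2 pi f * sqrt((p^2 + q^2) / 2)``.
    """
    p, q = freq_ratio
    rms = math.sqrt((p * p + q * q) / 2.0)
    return path_speed_um_s / (2.0 * math.pi * amplitude_um * rms)
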