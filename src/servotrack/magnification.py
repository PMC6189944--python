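"""Magnification-dependent optics model: pixel pitch vs. magnification ratio.

A zoom microscope with a continuously rotatable magnification dial changes
three optical parameters at once: the pixel pitch p (um/pixel on the sensor
grid), the focal distance d, and the required illumination l.  Only the
pixel pitch enters the tracking arithmetic directly (it converts image-space
error to stage-space error), so only p is modelled numerically here, from a
ten-point calibration table spanning 140x-1400x.  Focal distance and light
intensity are exposed as named stubs so a hardware port can attach its own
calibration curves; illumination variation is instead emulated by the scene
generator to exercise the adaptive threshold.

The interpolant is a shape-preserving monotone piecewise cubic (PCHIP): it
passes exactly through every calibration point and cannot overshoot, so the
physically required strict monotonicity (pitch decreases as magnification
increases) holds everywhere in range.  No extrapolation is allowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["MagnificationModel", "MagnificationRamp", "DEFAULT_CALIBRATION"]

#: Factory-calibrated (magnification ratio, pixel pitch um/pixel) pairs.
DEFAULT_CALIBRATION: tuple[tuple[float, float], ...] = (
    (140, 5.50),
    (210, 4.80),
    (280, 3.50),
    (420, 2.20),
    (560, 1.66),
    (700, 1.29),
    (840, 1.09),
    (980, 0.92),
    (1120, 0.85),
    (1400, 0.79),
)


class MagnificationModel:
    """Maps magnification ratio -> pixel pitch (and derived FOV size).

    Parameters
    ----------
    calibration : sequence of (ratio, pitch_um) pairs, optional
        Ratios must be strictly increasing, pitches strictly decreasing.
        Defaults to the embedded ten-point table.
    sensor_pixels : int
        Square sensor side in pixels (default 256).
    """

    def __init__(self, calibration=None, sensor_pixels: int = 256):
        if calibration is None:
            calibration = DEFAULT_CALIBRATION
        cal = np.asarray(calibration, dtype=float)
        if cal.ndim != 2 or cal.shape[1] != 2 or cal.shape[0] < 2:
            raise ValueError("calibration must be a list of (ratio, pitch) pairs")
        ratios, pitches = cal[:, 0], cal[:, 1]
        if not np.all(np.diff(ratios) > 0):
            raise ValueError("calibration ratios must be strictly increasing")
        if not np.all(np.diff(pitches) < 0):
            raise ValueError("calibration pitches must be strictly decreasing")
        if sensor_pixels <= 0:
            raise ValueError("sensor_pixels must be positive")
        self.ratios = ratios
        self.pitches = pitches
        self.sensor_pixels = int(sensor_pixels)
        self._interp = PchipInterpolator(ratios, pitches, extrapolate=False)

    @classmethod
    def from_csv(cls, path, sensor_pixels: int = 256) -> "MagnificationModel":
        """Load a calibration table from a CSV with columns ratio, pitch_um."""
        import pandas as pd

        df = pd.read_csv(path)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        if not {"ratio", "pitch_um"} <= set(cols):
            raise ValueError("calibration CSV needs columns 'ratio', 'pitch_um'")
        pairs = df[["ratio", "pitch_um"]].to_numpy(dtype=float)
        return cls(pairs, sensor_pixels=sensor_pixels)

    @property
    def ratio_range(self) -> tuple[float, float]:
        return float(self.ratios[0]), float(self.ratios[-1])

    def _check_range(self, ratio: float) -> None:
        lo, hi = self.ratio_range
        if not lo <= ratio <= hi:
            raise ValueError(
                f"magnification ratio {ratio} outside calibrated range [{lo}, {hi}]"
            )

    def pixel_pitch(self, ratio: float) -> float:
        """Pixel pitch in um/pixel at ``ratio``; exact at calibration points."""
        self._check_range(ratio)
        return float(self._interp(ratio))

    def fov_side(self, ratio: float) -> float:
        """Physical side length of the square FOV in um, rounded to 1 um.

        ``sensor_pixels * pixel_pitch(ratio)``: 1408 um at 140x down to
        202 um at 1400x with the default table.
        """
        return float(round(self.sensor_pixels * self.pixel_pitch(ratio)))

    # -- declared stubs: curves live in hardware-specific calibrations -------

    def focal_length(self, ratio: float) -> float:
        """Focal-distance component (stub; supply per-instrument curve)."""
        raise NotImplementedError(
            "focal-length calibration is hardware-specific; attach a curve"
        )

    def light_intensity(self, ratio: float) -> float:
        """Illumination component (stub; supply per-instrument curve)."""
        raise NotImplementedError(
            "light-intensity calibration is hardware-specific; attach a curve"
        )


@dataclass
class MagnificationRamp:
    """Continuous magnification change, linear in ratio over ``duration_s``.

    Models the seamless zoom between two dial positions; the full-range
    change takes about one second on the instrument this emulates, which is
    the default.  ``ratio(t)`` clamps outside [t0, t0 + duration_s].
    """

    from_ratio: float
    to_ratio: float
    t0: float = 0.0
    duration_s: float = 1.0

    def ratio(self, t: float) -> float:
        if self.duration_s <= 0 or t >= self.t0 + self.duration_s:
            return self.to_ratio
        if t <= self.t0:
            return self.from_ratio
        frac = (t - self.t0) / self.duration_s
        return self.from_ratio + frac * (self.to_ratio - self.from_ratio)
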