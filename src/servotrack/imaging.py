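"""Binary segmentation and image-moment measurement of a dark target.

The measurement chain is deliberately minimal so it can run inside a
millisecond-scale control loop: a grayscale frame is thresholded into a
binary foreground mask (dark target on bright background), and the target's
position and posture are read off the image moments of that mask,

    M_ij = sum_x sum_y x^i y^j I(x, y),

with the centre of gravity (COG) given by (M10/M00, M01/M00) and the
posture angle by half the two-argument arctangent of the order-2 central
moments.  No connected-component analysis is performed; restriction to a
region of interest is the only spatial filtering.

Pixel coordinates are 0-based with x = column (rightward) and y = row
(downward); the origin is the top-left pixel centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "Frame",
    "MomentSet",
    "TargetState",
    "NoTargetError",
    "binarize",
    "raw_moments",
    "centroid",
    "orientation",
    "measure",
]


class NoTargetError(ValueError):
    """Raised when a COG or posture is requested from an empty foreground."""


@dataclass(frozen=True)
class Frame:
    """One grayscale sensor frame.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W)
        Grayscale intensities in [0, 255]; 256 x 256 by default for the
        high-speed sensor this package emulates.
    t : float
        Capture time in seconds.
    pixel_pitch : float
        Physical sample spacing in um/pixel at the current magnification.
    frame_index : int
        Monotonically increasing capture counter.
    magnification : float or None
        Magnification ratio the frame was captured at, if known.
    """

    pixels: np.ndarray
    t: float = 0.0
    pixel_pitch: float = 5.50
    frame_index: int = 0
    magnification: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def center(self) -> tuple[float, float]:
        """Image centre (x, y) in pixel coordinates, the servo set-point."""
        h, w = self.pixels.shape
        return (w - 1) / 2.0, (h - 1) / 2.0


@dataclass(frozen=True)
class MomentSet:
    """Raw image moments up to order 2 plus the order-2 central moments.

    ``m00`` equals the number of foreground pixels counted.  An all-zero
    set (``m00 == 0``) is the well-defined "no target" value; consumers
    must check :attr:`is_empty` before dividing.
    """

    m00: float = 0.0
    m10: float = 0.0
    m01: float = 0.0
    m11: float = 0.0
    m20: float = 0.0
    m02: float = 0.0
    mu11: float = 0.0
    mu20: float = 0.0
    mu02: float = 0.0

    @property
    def is_empty(self) -> bool:
        return self.m00 == 0


@dataclass(frozen=True)
class TargetState:
    """The tracker's per-frame estimate of the target.

    ``xg, yg`` are the COG in pixel coordinates, ``phi`` the posture angle
    in radians in (-pi/2, pi/2] (an undirected body axis), ``area`` the
    foreground pixel count.
    """

    xg: float
    yg: float
    phi: float
    area: int
    frame_index: int = 0


def _as_pixels(frame: Frame | np.ndarray) -> np.ndarray:
    if isinstance(frame, Frame):
        return frame.pixels
    return np.asarray(frame)


def otsu_threshold(pixels: np.ndarray) -> float:
    """Otsu threshold of an 8-bit intensity sample (any shape).

    Computed on the 256-bin integer histogram so that a global additive
    illumination shift moves the threshold by exactly the same amount
    (no re-binning effects).
    """
    counts = np.bincount(pixels.reshape(-1), minlength=256)
    return float(threshold_otsu(hist=(counts, np.arange(256))))


def binarize(
    frame: Frame | np.ndarray,
    method: str = "adaptive",
    fixed_level: float | None = None,
) -> np.ndarray:
    """Convert a grayscale frame to a boolean foreground mask.

    Foreground (True) marks pixels at or below the threshold, i.e. the
    dark target under brightfield illumination.  With ``method="adaptive"``
    the threshold is recomputed from the frame's own histogram (global
    Otsu), which compensates for frame-to-frame illumination drift; a
    uniform frame yields an all-background mask.  With ``method="fixed"``,
    ``fixed_level`` is used verbatim (foreground strictly below the level).
    """
    px = _as_pixels(frame)
    if method == "fixed":
        if fixed_level is None:
            raise ValueError("fixed method requires fixed_level")
        return px < fixed_level
    if method != "adaptive":
        raise ValueError(f"unknown threshold method: {method!r}")
    if px.min() == px.max():
        return np.zeros(px.shape, dtype=bool)
    return px <= otsu_threshold(px)


def raw_moments(mask: np.ndarray, region=None) -> MomentSet:
    """Image moments of a binary mask, optionally restricted to a region.

    ``region`` is any object with a ``mask_within(mask)`` method (an
    :class:`~servotrack.roi.EllipseROI`); pixels outside it contribute
    nothing.  An empty foreground returns the empty :class:`MomentSet`.
    """
    mask = np.asarray(mask, dtype=bool)
    if region is not None:
        mask = region.mask_within(mask)
    ys, xs = np.nonzero(mask)
    m00 = xs.size
    if m00 == 0:
        return MomentSet()
    xs = xs.astype(np.float64)
    ys = ys.astype(np.float64)
    m10 = xs.sum()
    m01 = ys.sum()
    m11 = (xs * ys).sum()
    m20 = (xs * xs).sum()
    m02 = (ys * ys).sum()
    xbar = m10 / m00
    ybar = m01 / m00
    dx = xs - xbar
    dy = ys - ybar
    return MomentSet(
        m00=float(m00),
        m10=float(m10),
        m01=float(m01),
        m11=float(m11),
        m20=float(m20),
        m02=float(m02),
        mu11=float((dx * dy).sum()),
        mu20=float((dx * dx).sum()),
        mu02=float((dy * dy).sum()),
    )


def centroid(moments: MomentSet) -> tuple[float, float]:
    """COG ``(xg, yg) = (M10/M00, M01/M00)`` of a non-empty moment set."""
    if moments.is_empty:
        raise NoTargetError("empty foreground: COG undefined")
    return moments.m10 / moments.m00, moments.m01 / moments.m00


def orientation(moments: MomentSet) -> float:
    """Posture angle ``phi = atan2(2*mu11, mu20 - mu02) / 2`` in (-pi/2, pi/2].

    Central moments are used so the posture is invariant under translation
    of the target; the two-argument arctangent resolves the quadrant
    ambiguity of the half-angle.  A perfectly isotropic foreground
    (``mu11 == 0`` and ``mu20 == mu02``) returns 0 by convention.
    """
    if moments.is_empty:
        raise NoTargetError("empty foreground: posture undefined")
    num = 2.0 * moments.mu11
    den = moments.mu20 - moments.mu02
    if num == 0.0 and den == 0.0:
        return 0.0
    phi = 0.5 * math.atan2(num, den)
    # atan2 range (-pi, pi] halves to (-pi/2, pi/2] already
    return phi


def measure(mask: np.ndarray, region=None, frame_index: int = 0) -> TargetState | None:
    """Full measurement: moments -> COG + posture, or None if empty."""
    m = raw_moments(mask, region=region)
    if m.is_empty:
        return None
    xg, yg = centroid(m)
    return TargetState(
        xg=xg, yg=yg, phi=orientation(m), area=int(m.m00), frame_index=frame_index
    )
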