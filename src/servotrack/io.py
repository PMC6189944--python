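"""Reading and writing image stacks, masks and logs.

Offline tracking accepts 8-bit grayscale PNG or TIFF stacks (a multi-page
TIFF or a sorted list of single images) of dark targets on a bright
background; masks are exportable as PNG.  The servo loop is bypassed for
offline stacks (there is no stage to drive), but the full measurement
pipeline — thresholding, ROI propagation, moments — is identical.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .imaging import Frame
from .tracker import Mode, Tracker, TrackerConfig

__all__ = ["load_stack", "save_mask_png", "track_stack"]


def _to_gray8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:  # channel mean; inputs are expected to be grayscale
        img = img[..., :3].mean(axis=-1)
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img


def load_stack(
    path, pixel_pitch: float = 5.50, dt: float = 1.0 / 500.0
) -> list[Frame]:
    """Load a grayscale stack into :class:`Frame` objects.

    ``path`` may be a multi-page TIFF, a single image, or a directory of
    PNG/TIFF files (sorted by name).  ``pixel_pitch`` and ``dt`` supply the
    physical metadata the files do not carry.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF files in {path}")
        images = [_to_gray8(iio.imread(f)) for f in files]
    elif path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        pages = data if data.ndim == 3 else [data]
        images = [_to_gray8(p) for p in pages]
    else:
        images = [_to_gray8(iio.imread(path))]
    return [
        Frame(pixels=img, t=i * dt, pixel_pitch=pixel_pitch, frame_index=i)
        for i, img in enumerate(images)
    ]


def save_mask_png(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit PNG (foreground = 255)."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def track_stack(frames: list[Frame], config: TrackerConfig | None = None) -> Tracker:
    """Run the measurement pipeline over a pre-recorded stack (no servo).

    The tracker starts in TRACK mode (the stack is assumed to already show
    the target) and its per-frame record is returned via the tracker.
    """
    config = config or TrackerConfig(start_mode=Mode.TRACK)
    tracker = Tracker(config)
    for frame in frames:
        tracker.update(frame)
    return tracker
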