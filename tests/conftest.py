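import numpy as np
import pytest

from servotrack.magnification import MagnificationModel


@pytest.fixture(scope="session")
def optics():
    return MagnificationModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_moments(mask):
    """Independent double-loop oracle for raw and central image moments."""
    m = {k: 0.0 for k in ("m00", "m10", "m01", "m11", "m20", "m02")}
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                m["m00"] += 1
                m["m10"] += x
                m["m01"] += y
                m["m11"] += x * y
                m["m20"] += x * x
                m["m02"] += y * y
    if m["m00"] == 0:
        return {**m, "mu11": 0.0, "mu20": 0.0, "mu02": 0.0}
    xb = m["m10"] / m["m00"]
    yb = m["m01"] / m["m00"]
    mu = {"mu11": 0.0, "mu20": 0.0, "mu02": 0.0}
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                mu["mu11"] += (x - xb) * (y - yb)
                mu["mu20"] += (x - xb) ** 2
                mu["mu02"] += (y - yb) ** 2
    return {**m, **mu}


def ellipse_mask(shape, cx, cy, a, b, angle):
    """Pixel-centre membership mask of a rotated ellipse (test geometry)."""
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = xs - cx
    dy = ys - cy
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0
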