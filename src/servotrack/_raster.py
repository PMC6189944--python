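"""Rasterization kernels for the scene renderer.

Hot path of the closed-loop simulator: compiled with numba when available
(a few us per shape), with equivalent pure-numpy fallbacks otherwise.
Results are identical between the two paths: the ellipse is blended by
ss x ss area-coverage supersampling with round-half-to-even, the circle is
a hard-edged fill.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _ellipse_kernel(img, cx, cy, ha, hb, ca, sa, intensity, x0, x1, y0, y1, ss):
    inv = 1.0 / ss
    for y in range(y0, y1):
        for x in range(x0, x1):
            cnt = 0
            for i in range(ss):
                py = y + (i + 0.5) * inv - 0.5 - cy
                for j in range(ss):
                    px = x + (j + 0.5) * inv - 0.5 - cx
                    u = (px * ca + py * sa) / ha
                    v = (-px * sa + py * ca) / hb
                    if u * u + v * v <= 1.0:
                        cnt += 1
            if cnt > 0:
                cov = cnt * inv * inv
                val = img[y, x] * (1.0 - cov) + intensity * cov
                img[y, x] = np.uint8(np.rint(val))


@njit(cache=True)
def _circles_kernel(img, circles, intensity):
    h, w = img.shape
    for k in range(circles.shape[0]):
        cx = circles[k, 0]
        cy = circles[k, 1]
        r = circles[k, 2]
        x0 = max(int(np.floor(cx - r)), 0)
        x1 = min(int(np.ceil(cx + r)) + 1, w)
        y0 = max(int(np.floor(cy - r)), 0)
        y1 = min(int(np.ceil(cy + r)) + 1, h)
        r2 = r * r
        for y in range(y0, y1):
            dy = y - cy
            for x in range(x0, x1):
                dx = x - cx
                if dx * dx + dy * dy <= r2:
                    img[y, x] = intensity


def _ellipse_numpy(img, cx, cy, ha, hb, ca, sa, intensity, x0, x1, y0, y1, ss):
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    xs = np.arange(x0, x1, dtype=float)
    ys = np.arange(y0, y1, dtype=float)
    X = (xs[None, :, None] + offs[None, None, :] - cx)[:, :, :, None]
    Y = (ys[:, None, None] + offs[None, None, :] - cy)[:, :, None, :]
    U = (X * ca + Y * sa) / ha
    V = (-X * sa + Y * ca) / hb
    cov = (U * U + V * V <= 1.0).mean(axis=(2, 3))
    patch = img[y0:y1, x0:x1].astype(float)
    blended = patch * (1.0 - cov) + intensity * cov
    img[y0:y1, x0:x1] = np.rint(blended).astype(img.dtype)


def _circles_numpy(img, circles, intensity):
    h, w = img.shape
    for cx, cy, r in circles:
        x0 = max(int(np.floor(cx - r)), 0)
        x1 = min(int(np.ceil(cx + r)) + 1, w)
        y0 = max(int(np.floor(cy - r)), 0)
        y1 = min(int(np.ceil(cy + r)) + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1, dtype=float) - cx
        ys = np.arange(y0, y1, dtype=float) - cy
        inside = xs[None, :] ** 2 + ys[:, None] ** 2 <= r * r
        img[y0:y1, x0:x1][inside] = intensity


def fill_ellipse_aa(img, cx, cy, ha, hb, angle, intensity, ss=4):
    """Blend a rotated ellipse into the uint8 image by area coverage."""
    import math

    h, w = img.shape
    ca, sa = math.cos(angle), math.sin(angle)
    ex = math.hypot(ha * ca, hb * sa) + 1.0
    ey = math.hypot(ha * sa, hb * ca) + 1.0
    x0 = max(int(math.floor(cx - ex)), 0)
    x1 = min(int(math.ceil(cx + ex)) + 1, w)
    y0 = max(int(math.floor(cy - ey)), 0)
    y1 = min(int(math.ceil(cy + ey)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    fn = _ellipse_kernel if HAVE_NUMBA else _ellipse_numpy
    fn(img, float(cx), float(cy), float(ha), float(hb), ca, sa,
       float(intensity), x0, x1, y0, y1, int(ss))


def fill_circles(img, circles, intensity):
    """Hard-edged fill of (cx, cy, r) circles into the uint8 image."""
    if not len(circles):
        return
    arr = np.asarray(circles, dtype=np.float64).reshape(-1, 3)
    if HAVE_NUMBA:
        _circles_kernel(img, arr, np.uint8(intensity))
    else:
        _circles_numpy(img, arr, np.uint8(intensity))
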