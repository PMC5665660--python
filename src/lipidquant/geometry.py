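"""Shared rasterization primitives (disks, octagons).

Pixel-center convention throughout: a pixel (r, c) is treated as the point
(r, c) in continuous coordinates, 0-based, origin at the top-left.
"""

from __future__ import annotations

import math

import numpy as np

_OCT_APOTHEM = math.cos(math.pi / 8)  # apothem / circumradius of a regular octagon


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean (2r+1, 2r+1) structuring element: centers within Euclidean
    distance ``radius`` of the element center."""
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return rr * rr + cc * cc <= radius * radius


def rasterize_disk(
    center: tuple[float, float], radius: float, image_shape: tuple[int, int]
) -> np.ndarray:
    """Pixels whose centers lie within Euclidean ``radius`` of ``center``,
    clipped to the image. Returns an (n, 2) int array of (row, col)."""
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    h, w = image_shape
    r0, c0 = center
    rlo = max(0, int(math.floor(r0 - radius)))
    rhi = min(h - 1, int(math.ceil(r0 + radius)))
    clo = max(0, int(math.floor(c0 - radius)))
    chi = min(w - 1, int(math.ceil(c0 + radius)))
    if rhi < rlo or chi < clo:
        return np.empty((0, 2), dtype=np.intp)
    rr, cc = np.mgrid[rlo : rhi + 1, clo : chi + 1]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius * radius
    return np.column_stack([rr[inside], cc[inside]])


def octagon_offsets(circumradius: float) -> np.ndarray:
    """(row, col) offsets covered by a flat-top regular octagon of the given
    circumradius centered on a pixel.

    A pixel is included when its center satisfies all eight half-plane
    constraints pushed out by half a pixel (apothem + 0.5), so the stamp of
    circumradius 1 is the full 8-neighborhood + center and circumradius 0 is
    the single center pixel.
    """
    if circumradius < 0:
        raise ValueError(f"circumradius must be >= 0, got {circumradius}")
    a = circumradius * _OCT_APOTHEM + 0.5
    n = int(math.ceil(a))
    rr, cc = np.mgrid[-n : n + 1, -n : n + 1]
    ax = np.abs(cc)
    ay = np.abs(rr)
    inside = (ax <= a) & (ay <= a) & ((ax + ay) / math.sqrt(2) <= a)
    return np.column_stack([rr[inside], cc[inside]])
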