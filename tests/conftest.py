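import math

import numpy as np
import pytest

from retimorph import BinaryMask


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def angled_bar(width: float, angle_deg: float, size: int = 90) -> np.ndarray:
    """A straight bar of nominal perpendicular width ``width`` px."""
    th = math.radians(angle_deg)
    d = np.array([math.sin(th), math.cos(th)])
    n = np.array([-d[1], d[0]])
    c = np.array([size / 2, size / 2])
    yy, xx = np.mgrid[0:size, 0:size]
    pts = np.stack([yy, xx], -1) - c
    return ((np.abs(pts @ n) <= width / 2 - 0.5 + 1e-9) & (np.abs(pts @ d) <= size * 0.45)).astype(
        bool
    )


def brute_force_box_count(pixels: np.ndarray, size: int, offset: int = 0) -> int:
    """Count occupied boxes by scanning every box slice (independent oracle)."""
    h, w = pixels.shape
    count = 0
    r = -offset
    while r < h:
        c = -offset
        while c < w:
            if pixels[max(r, 0) : r + size, max(c, 0) : c + size].any():
                count += 1
            c += size
        r += size
    return count


@pytest.fixture()
def checkerboard():
    tile = 10
    m = np.zeros((80, 80), dtype=bool)
    for i in range(8):
        for j in range(8):
            if (i + j) % 2 == 0:
                m[i * tile : (i + 1) * tile, j * tile : (j + 1) * tile] = True
    return BinaryMask(m, name="checkerboard")
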