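"""Shared fixtures: a naive thinning oracle and random mask generators."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.draw import disk


def naive_thin(mask: np.ndarray) -> np.ndarray:
    """Straightforward per-pixel reference implementation of the thinning rules.

    Deliberately written with plain Python loops and explicit neighbor
    reads so it shares no code path with the vectorized implementation.
    """
    g = (np.asarray(mask) != 0).astype(int).tolist()
    rows, cols = len(g), len(g[0])

    def px(r: int, c: int) -> int:
        return g[r][c] if 0 <= r < rows and 0 <= c < cols else 0

    while True:
        deleted = False
        for sub in (1, 2):
            dels = []
            for r in range(rows):
                for c in range(cols):
                    if not g[r][c]:
                        continue
                    p2, p3, p4, p5 = px(r - 1, c), px(r - 1, c + 1), px(r, c + 1), px(r + 1, c + 1)
                    p6, p7, p8, p9 = px(r + 1, c), px(r + 1, c - 1), px(r, c - 1), px(r - 1, c - 1)
                    ring = [p2, p3, p4, p5, p6, p7, p8, p9, p2]
                    b = sum(ring[:-1])
                    a = sum(1 for u, v in zip(ring[:-1], ring[1:]) if u == 0 and v == 1)
                    if not (2 <= b <= 6 and a == 1):
                        continue
                    if sub == 1:
                        if p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0:
                            dels.append((r, c))
                    else:
                        if p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0:
                            dels.append((r, c))
            for r, c in dels:
                g[r][c] = 0
            deleted = deleted or bool(dels)
        if not deleted:
            break
    return np.array(g, dtype=np.uint8)


def random_disk_mask(seed: int, shape: tuple[int, int] = (32, 32)) -> np.ndarray:
    """Union of 1-4 random disks (radius 2-5): blob-like shapes with interior."""
    rng = np.random.default_rng(seed)
    m = np.zeros(shape, dtype=np.uint8)
    for _ in range(int(rng.integers(1, 5))):
        r, c = (int(v) for v in rng.integers(3, shape[0] - 3, 2))
        rr, cc = disk((r, c), int(rng.integers(2, 6)), shape=shape)
        m[rr, cc] = 1
    return m


def random_stroke_mask(seed: int, shape: tuple[int, int] = (32, 32)) -> np.ndarray:
    """Random-walk strokes painted with a 3x3 brush; may be thin in places."""
    rng = np.random.default_rng(seed)
    m = np.zeros(shape, dtype=bool)
    for _ in range(int(rng.integers(1, 4))):
        r, c = (int(v) for v in rng.integers(4, shape[0] - 4, 2))
        for _ in range(int(rng.integers(10, 40))):
            m[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2] = True
            dr, dc = (int(v) for v in rng.integers(-1, 2, 2))
            r = int(np.clip(r + dr, 1, shape[0] - 2))
            c = int(np.clip(c + dc, 1, shape[1] - 2))
    return m.astype(np.uint8)


@pytest.fixture(scope="session")
def default_scene():
    """One 3-shoot scene with its noise-free rendering (seed 7)."""
    from teapick import scene

    truth = scene.build_scene(3, rng=7)
    rendered = scene.render(truth)
    return truth, rendered
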