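"""Binarization and fast parallel (two-subiteration) thinning.

The picking-point pipeline needs unit-width skeletons of side-view tea
shoots.  Skeletons are produced by the classic fast parallel thinning
scheme: two subiterations per pass, each deleting boundary pixels whose
8-neighborhood satisfies a small set of conditions, with all deletion
decisions of a subiteration taken on the grid state at the start of that
subiteration.  The pass is repeated until a fixpoint is reached.

Conventions: images are 2-D numpy arrays indexed ``[row, col]``; masks and
skeletons are ``uint8`` arrays over {0, 1}.  The neighbor ring around a
pixel P1 is ordered clockwise starting north::

    P9 P2 P3
    P8 P1 P4
    P7 P6 P5
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["binarize", "neighbor_stats", "thin"]


def binarize(image: np.ndarray, method: str = "otsu", threshold: int | None = None) -> np.ndarray:
    """Threshold a grayscale image; the brighter class becomes foreground.

    Parameters
    ----------
    image
        2-D grayscale array.
    method
        ``"otsu"`` (default, parameter-free) or ``"fixed"``.
    threshold
        Required for ``"fixed"``; gray levels strictly above it are
        foreground.  Must lie in [0, 255].

    Returns
    -------
    ``uint8`` mask over {0, 1} with the same shape as ``image``.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if method == "otsu":
        if image.min() == image.max():
            warnings.warn(
                "constant image: Otsu threshold undefined, returning all-background mask",
                stacklevel=2,
            )
            return np.zeros(image.shape, dtype=np.uint8)
        t = threshold_otsu(image)
    elif method == "fixed":
        if threshold is None or not (0 <= threshold <= 255):
            raise ValueError("fixed method requires a threshold in [0, 255]")
        t = threshold
    else:
        raise ValueError(f"unknown binarization method: {method!r}")
    return (image > t).astype(np.uint8)


def _ring(grid: np.ndarray) -> list[np.ndarray]:
    """Neighbor planes P2..P9 (clockwise from north) for every pixel."""
    return [
        np.roll(grid, 1, axis=0),                 # P2 = N
        np.roll(grid, (1, -1), axis=(0, 1)),      # P3 = NE
        np.roll(grid, -1, axis=1),                # P4 = E
        np.roll(grid, (-1, -1), axis=(0, 1)),     # P5 = SE
        np.roll(grid, -1, axis=0),                # P6 = S
        np.roll(grid, (-1, 1), axis=(0, 1)),      # P7 = SW
        np.roll(grid, 1, axis=1),                 # P8 = W
        np.roll(grid, (1, 1), axis=(0, 1)),       # P9 = NW
    ]


def neighbor_stats(mask: np.ndarray, pixel: tuple[int, int]) -> tuple[int, int]:
    """Return ``(B, A)`` for one pixel of a binary mask.

    ``B`` is the number of foreground 8-neighbors; ``A`` is the number of
    0->1 transitions in the ordered ring P2, P3, ..., P9, P2.  A 1-pixel
    background border is assumed around the grid, so pixels on the mask
    edge are handled without special cases.
    """
    mask = np.asarray(mask)
    r, c = pixel
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        raise IndexError(f"pixel {pixel} outside mask of shape {mask.shape}")
    padded = np.pad(mask != 0, 1)
    pr, pc = r + 1, c + 1
    ring = [
        padded[pr - 1, pc], padded[pr - 1, pc + 1], padded[pr, pc + 1],
        padded[pr + 1, pc + 1], padded[pr + 1, pc], padded[pr + 1, pc - 1],
        padded[pr, pc - 1], padded[pr - 1, pc - 1],
    ]
    b = int(sum(ring))
    closed = ring + [ring[0]]
    a = int(sum((not u) and v for u, v in zip(closed[:-1], closed[1:])))
    return b, a


def thin(mask: np.ndarray) -> np.ndarray:
    """Reduce a binary mask to a unit-width skeleton (fast parallel thinning).

    Each pass runs two subiterations.  A foreground pixel P1 is deleted iff
    2 <= B(P1) <= 6, A(P1) == 1, and

    * subiteration 1: P2*P4*P6 == 0 and P4*P6*P8 == 0  (south-east boundary
      and north-west corner pixels), or
    * subiteration 2: P2*P4*P8 == 0 and P2*P6*P8 == 0  (north-west boundary
      and south-east corner pixels).

    Deletions within a subiteration are computed from the grid state at the
    start of that subiteration (parallel semantics).  Passes repeat until no
    pixel is deleted; the input is not modified.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    # Pad one background ring so the neighbor rolls never wrap foreground.
    grid = np.pad(mask != 0, 1)
    while True:
        deleted_any = False
        for sub in (0, 1):
            p2, p3, p4, p5, p6, p7, p8, p9 = _ring(grid)
            ring = [p2, p3, p4, p5, p6, p7, p8, p9, p2]
            b = sum(p.astype(np.uint8) for p in ring[:-1])
            a = sum((~u & v).astype(np.uint8) for u, v in zip(ring[:-1], ring[1:]))
            cond = grid & (b >= 2) & (b <= 6) & (a == 1)
            if sub == 0:
                cond &= ~(p2 & p4 & p6) & ~(p4 & p6 & p8)
            else:
                cond &= ~(p2 & p4 & p8) & ~(p2 & p6 & p8)
            if cond.any():
                grid &= ~cond
                deleted_any = True
        if not deleted_any:
            break
    return grid[1:-1, 1:-1].astype(np.uint8)
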