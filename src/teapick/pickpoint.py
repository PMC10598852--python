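"""Picking-point localization from detection boxes and skeletons.

Given a side-view image of strip-clamped tea shoots and a detection box per
shoot, the pipeline crops the box, binarizes and thins it, scans the
skeleton top-to-bottom for the bud-leaf intersection (the first row holding
two or more skeleton pixels), traces the stem skeleton downward, fits a
growth curve column = f(row), steps 4 mm down that curve to the picking
point, and maps the result to the world frame of the picking mechanism.

Pixel convention: arrays are indexed ``[row, col]`` with the origin at the
top-left corner; rows (the Z axis) increase downward, columns (the X axis)
increase rightward, boxes are half-open ``[min, max)``.  World coordinates
are millimetres in the same orientation.  The vertical calibration is the
proportionality Zt / Ht = Zs / Hs between the pixel height of a point and
its physical height inside the shooting area; the horizontal axis uses the
same mm/px scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

from .skeleton import binarize, thin

__all__ = [
    "DetectionBox",
    "CameraCalibration",
    "StemTrace",
    "GrowthCurve",
    "PickPoint",
    "LocateConfig",
    "LocateResult",
    "find_intersection",
    "trace_stem",
    "fit_growth_curve",
    "locate_pick_point_px",
    "pixel_to_world",
    "world_to_pixel",
    "blade_displacement",
    "locate_all",
]


@dataclass(frozen=True)
class DetectionBox:
    """Axis-aligned detection box in pixel coordinates, half-open [min, max)."""

    class_id: int
    x_min: int
    z_min: int
    x_max: int
    z_max: int
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.z_min < self.z_max):
            raise ValueError(f"degenerate box: {self}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence outside [0, 1]: {self.confidence}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.z_max - self.z_min

    @property
    def center(self) -> tuple[float, float]:
        """(x, z) center in pixel coordinates."""
        return (self.x_min + self.width / 2.0, self.z_min + self.height / 2.0)

    def fits_inside(self, shape: tuple[int, int]) -> bool:
        rows, cols = shape
        return self.x_min >= 0 and self.z_min >= 0 and self.x_max <= cols and self.z_max <= rows


@dataclass(frozen=True)
class CameraCalibration:
    """Pixel-to-world calibration of the shooting area.

    Parameters
    ----------
    Ht
        Image height in pixels.
    Hs
        Physical height of the shooting area in mm (default 196).
    Hz
        Height of the picking blade above the window base when the picker
        is parked at its top position, in mm (default 212).
    x_scale
        Horizontal scale in mm/px; defaults to ``Hs / Ht`` (the vertical
        scale, i.e. square pixels).
    """

    Ht: int
    Hs: float = 196.0
    Hz: float = 212.0
    x_scale: float | None = None

    def __post_init__(self) -> None:
        if self.Ht <= 0 or self.Hs <= 0:
            raise ValueError("Ht and Hs must be positive")
        if self.Hz < self.Hs:
            raise ValueError("Hz must be >= Hs (blade parks above the window)")
        if self.x_scale is None:
            object.__setattr__(self, "x_scale", self.Hs / self.Ht)

    @property
    def mm_per_px(self) -> float:
        return self.Hs / self.Ht

    @property
    def px_per_mm(self) -> float:
        return self.Ht / self.Hs


@dataclass
class StemTrace:
    """Ordered skeleton walk from the bud-leaf intersection downward."""

    path: np.ndarray  # (N, 2) int array of (row, col)
    arc_length_px: float
    flags: list[str] = field(default_factory=list)


@dataclass
class GrowthCurve:
    """Least-squares polynomial stem centerline, column as a function of row."""

    poly: Polynomial
    valid_rows: tuple[float, float]
    fit_residual: float
    degree: int

    def __call__(self, row: float | np.ndarray) -> float | np.ndarray:
        return self.poly(row)


@dataclass
class PickPoint:
    """A localized picking point in pixel and world coordinates."""

    pixel: tuple[float, float]          # (Xt, Zt) px, full-image frame
    world: tuple[float, float]          # (Xs, Zs) mm
    source_box: DetectionBox
    intersection_px: tuple[float, float]     # (Xt, Zt) of the bud-leaf intersection
    intersection_world: tuple[float, float]  # same point in mm
    flags: list[str] = field(default_factory=list)


def find_intersection(
    skeleton: np.ndarray, box: DetectionBox
) -> tuple[tuple[int, int], list[str]]:
    """Locate the bud-leaf intersection inside a detection box.

    Rows are scanned top to bottom; the scan stops at the first row that
    contains at least two skeleton pixels — above the intersection only the
    single bud line is present, below it the leaf branches appear.  Within
    the stop row the returned pixel is the one nearest the actual skeleton
    junction (a pixel with >= 3 skeleton neighbors at or below the stop
    row); if no junction pixel exists nearby, the pixel nearest the row's
    median column is used.

    Returns ``((row, col), flags)`` in the coordinates of ``skeleton``.
    A shoot whose skeleton never doubles up (a leafless stalk) degrades to
    the lowest single-pixel row and is flagged ``"no_junction"``.
    """
    skeleton = np.asarray(skeleton)
    if not box.fits_inside(skeleton.shape):
        raise ValueError(f"box {box} outside skeleton of shape {skeleton.shape}")
    sub = skeleton[box.z_min:box.z_max, box.x_min:box.x_max] != 0
    if not sub.any():
        raise ValueError("detection box contains no skeleton pixels")

    counts = sub.sum(axis=1)
    multi = np.nonzero(counts >= 2)[0]
    if multi.size == 0:
        row = int(np.nonzero(counts >= 1)[0][-1])
        col = int(np.nonzero(sub[row])[0][0])
        return (row + box.z_min, col + box.x_min), ["no_junction"]

    row = int(multi[0])
    cols = np.nonzero(sub[row])[0]
    median_col = float(np.median(cols))

    # Junction pixels: skeleton pixels at or below the stop row whose 3x3
    # ring holds >= 3 skeleton neighbors.  The topmost one anchors the
    # choice of pixel within the stop row.
    padded = np.pad(sub, 1)
    neigh = (
        padded[:-2, :-2].astype(np.int8) + padded[:-2, 1:-1] + padded[:-2, 2:]
        + padded[1:-1, :-2] + padded[1:-1, 2:]
        + padded[2:, :-2] + padded[2:, 1:-1] + padded[2:, 2:]
    )
    junction = sub & (neigh >= 3)
    junction[:row] = False
    jr, jc = np.nonzero(junction)
    if jr.size:
        top = jr.min()
        anchor = float(np.median(jc[jr == top]))
        col = int(cols[np.argmin(np.abs(cols - anchor))])
    else:
        col = int(cols[np.argmin(np.abs(cols - median_col))])
    return (row + box.z_min, col + box.x_min), []


_NEIGHBOR_STEPS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _downward_reach(
    skeleton: np.ndarray,
    start: tuple[int, int],
    visited: set[tuple[int, int]],
    bounds: tuple[int, int, int, int],
) -> int:
    """Deepest row reachable from ``start`` along unvisited skeleton pixels."""
    r_lo, r_hi, c_lo, c_hi = bounds
    seen = set(visited)
    stack = [start]
    seen.add(start)
    deepest = start[0]
    while stack:
        r, c = stack.pop()
        deepest = max(deepest, r)
        for dr, dc in _NEIGHBOR_STEPS:
            nr, nc = r + dr, c + dc
            if r_lo <= nr < r_hi and c_lo <= nc < c_hi:
                if (nr, nc) not in seen and skeleton[nr, nc]:
                    seen.add((nr, nc))
                    stack.append((nr, nc))
    return deepest


def trace_stem(
    skeleton: np.ndarray, start: tuple[int, int], box: DetectionBox
) -> StemTrace:
    """Walk the skeleton downward from the intersection toward the stem base.

    At each step the walk takes the unvisited 8-neighbor that maximizes
    downward progress.  Where several branches leave a junction, progress
    is measured as the deepest row each branch can eventually reach
    (leaf branches dead-end a few millimetres down, the stalk continues to
    the bottom of the box); remaining ties are broken by the smallest
    column deviation from the current heading.  The walk ends at a dead
    end, the bottom of the box, or the image edge.  Traces shorter than
    3 pixels are flagged ``"short_trace"``.
    """
    skeleton = np.asarray(skeleton)
    r, c = int(start[0]), int(start[1])
    if skeleton[r, c] == 0:
        raise ValueError(f"start {start} is not a skeleton pixel")
    rows, cols = skeleton.shape
    bounds = (box.z_min, min(box.z_max, rows), box.x_min, min(box.x_max, cols))
    path = [(r, c)]
    visited = {(r, c)}
    arc = 0.0
    heading_dc = 0  # last column step; initial heading is straight down
    while r < box.z_max - 1:
        candidates = []
        for dr, dc in _NEIGHBOR_STEPS:
            nr, nc = r + dr, c + dc
            if not (bounds[0] <= nr < bounds[1] and bounds[2] <= nc < bounds[3]):
                continue
            if (nr, nc) in visited or skeleton[nr, nc] == 0:
                continue
            candidates.append((dr, dc))
        if not candidates:
            break
        if len(candidates) == 1:
            dr, dc = candidates[0]
        else:
            scored = []
            for dr, dc in candidates:
                reach = _downward_reach(
                    skeleton, (r + dr, c + dc), visited, bounds
                )
                scored.append((-reach, -dr, abs(dc - heading_dc), (dr, dc)))
            dr, dc = min(scored)[-1]
        r, c = r + dr, c + dc
        path.append((r, c))
        visited.add((r, c))
        arc += float(np.hypot(dr, dc))
        heading_dc = dc
    flags = ["short_trace"] if len(path) < 3 else []
    return StemTrace(path=np.asarray(path, dtype=int), arc_length_px=arc, flags=flags)


def fit_growth_curve(trace: StemTrace, degree: int = 3) -> GrowthCurve:
    """Fit the stem growth curve column = f(row) by least squares.

    The requested degree is reduced to ``len(trace) - 1`` when the trace is
    short (down to degree 0 for a vertical two-pixel stub), so the fit is
    always well-posed.
    """
    path = np.asarray(trace.path)
    if len(path) < 2:
        raise ValueError("trace must contain at least 2 points")
    rows = path[:, 0].astype(float)
    cols = path[:, 1].astype(float)
    deg = int(min(degree, len(path) - 1, len(np.unique(rows)) - 1))
    deg = max(deg, 0)
    if np.ptp(cols) == 0:
        deg = 0  # perfectly vertical stem: constant column

    poly = Polynomial.fit(rows, cols, deg)
    residual = float(np.sqrt(np.mean((poly(rows) - cols) ** 2)))
    return GrowthCurve(
        poly=poly,
        valid_rows=(float(rows.min()), float(rows.max())),
        fit_residual=residual,
        degree=deg,
    )


def locate_pick_point_px(
    curve: GrowthCurve,
    start: tuple[float, float],
    offset_mm: float = 4.0,
    calib: CameraCalibration | None = None,
    mode: str = "vertical",
) -> tuple[tuple[float, float], list[str]]:
    """Step ``offset_mm`` down the growth curve from the intersection.

    ``start`` is the intersection as ``(row, col)``.  The offset is a
    vertical drop toward the stalk base: ``dz_px = offset_mm * Ht / Hs``
    (20 px for the default 4 mm at Ht=980 px over Hs=196 mm).  With
    ``mode="arc"`` the offset is measured along the curve's arc length
    instead.  Target rows beyond the fitted range are clamped and flagged.

    Returns ``((row, col), flags)``.
    """
    if calib is None:
        raise ValueError("calibration is required to convert mm to pixels")
    if offset_mm < 0:
        raise ValueError("offset_mm must be >= 0")
    start_row = float(start[0])
    flags: list[str] = []
    if mode == "vertical":
        target_row = start_row + offset_mm * calib.px_per_mm
    elif mode == "arc":
        target_px = offset_mm * calib.px_per_mm
        step = 0.25
        row, travelled = start_row, 0.0
        while travelled < target_px:
            d_col = float(curve(row + step)) - float(curve(row))
            travelled += float(np.hypot(step, d_col))
            row += step
        target_row = row
    else:
        raise ValueError(f"unknown offset mode: {mode!r}")
    lo, hi = curve.valid_rows
    if not (lo <= target_row <= hi):
        flags.append("offset_clamped")
        target_row = min(max(target_row, lo), hi)
    return (target_row, float(curve(target_row))), flags


def pixel_to_world(point: tuple[float, float], calib: CameraCalibration) -> tuple[float, float]:
    """Map an ``(Xt, Zt)`` pixel point to ``(Xs, Zs)`` in mm.

    Vertical: Zs = Zt * Hs / Ht (similar triangles of the shooting area);
    horizontal: Xs = Xt * x_scale.  The map is exactly linear.
    """
    xt, zt = point
    return (xt * calib.x_scale, zt * calib.Hs / calib.Ht)


def world_to_pixel(point: tuple[float, float], calib: CameraCalibration) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_world`."""
    xs, zs = point
    return (xs / calib.x_scale, zs * calib.Ht / calib.Hs)


def blade_displacement(
    z_next_mm: float, calib: CameraCalibration, z_prev_mm: float | None = None
) -> float:
    """Signed vertical blade travel (mm, positive downward) to reach a point.

    From the parked top position the blade sits ``Hz`` above the window
    base, i.e. ``Hz - Hs`` above the window top, so the first move is
    ``(Hz - Hs) + z_next``.  Between consecutive picks the previous picking
    height is the new reference and the travel is ``z_next - z_prev``.
    """
    if not (0.0 <= z_next_mm <= calib.Hs):
        raise ValueError(f"target height {z_next_mm} mm outside shooting window [0, {calib.Hs}]")
    if z_prev_mm is None:
        return (calib.Hz - calib.Hs) + z_next_mm
    return z_next_mm - z_prev_mm


@dataclass
class LocateConfig:
    """Configuration for :func:`locate_all`.

    ``fov_width_px`` enables the central field-of-view filter used by the
    continuously moving rig (boxes whose center falls outside a central
    vertical strip of this width are skipped); ``None`` disables the
    filter, which is the library default so that every supplied box is
    processed.
    """

    offset_mm: float = 4.0
    fov_width_px: int | None = None
    binarize_method: str = "otsu"
    threshold: int | None = None
    degree: int = 3
    offset_mode: str = "vertical"


@dataclass
class LocateResult:
    """Pick points plus an explicit record of skipped or degenerate boxes."""

    points: list[PickPoint]
    skipped: list[tuple[DetectionBox, str]]


def locate_all(
    image: np.ndarray,
    boxes: list[DetectionBox],
    calib: CameraCalibration | None = None,
    config: LocateConfig | None = None,
) -> LocateResult:
    """Run the full localization pipeline over every detection box.

    Per box: crop, binarize, thin, find the bud-leaf intersection, trace
    the stem, fit the growth curve, step the offset down the curve, map to
    full-image pixels and to world mm.  Boxes that cannot be processed are
    reported in ``skipped`` with a reason, never silently dropped.
    """
    image = np.asarray(image)
    config = config or LocateConfig()
    if calib is None:
        calib = CameraCalibration(Ht=image.shape[0])
    if calib.Ht != image.shape[0]:
        raise ValueError(
            f"calibration Ht={calib.Ht} does not match image height {image.shape[0]}"
        )
    points: list[PickPoint] = []
    skipped: list[tuple[DetectionBox, str]] = []
    center_x = image.shape[1] / 2.0
    for box in boxes:
        if not box.fits_inside(image.shape):
            raise ValueError(f"box {box} outside image of shape {image.shape}")
        if config.fov_width_px is not None:
            if abs(box.center[0] - center_x) > config.fov_width_px / 2.0:
                skipped.append((box, "outside_field_of_view"))
                continue
        crop = image[box.z_min:box.z_max, box.x_min:box.x_max]
        mask = binarize(crop, method=config.binarize_method, threshold=config.threshold)
        if not mask.any():
            skipped.append((box, "empty_mask"))
            continue
        skel = thin(mask)
        local_box = DetectionBox(box.class_id, 0, 0, box.width, box.height)
        try:
            (ir, ic), flags = find_intersection(skel, local_box)
        except ValueError as exc:
            skipped.append((box, str(exc)))
            continue
        trace = trace_stem(skel, (ir, ic), local_box)
        flags += trace.flags
        if len(trace.path) < 2:
            skipped.append((box, "trace_too_short"))
            continue
        curve = fit_growth_curve(trace, degree=config.degree)
        (pr, pc), off_flags = locate_pick_point_px(
            curve, (ir, ic), config.offset_mm, calib, mode=config.offset_mode
        )
        flags += off_flags
        pick_px = (pc + box.x_min, pr + box.z_min)
        inter_px = (float(ic + box.x_min), float(ir + box.z_min))
        points.append(
            PickPoint(
                pixel=pick_px,
                world=pixel_to_world(pick_px, calib),
                source_box=box,
                intersection_px=inter_px,
                intersection_world=pixel_to_world(inter_px, calib),
                flags=flags,
            )
        )
    return LocateResult(points=points, skipped=skipped)
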