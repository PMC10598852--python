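"""Synthetic side-view tea-row scenes with exact ground truth.

The generator emulates the geometry of strip-clamped tea shoots seen from
the side by the picking rig's camera: each shoot is a gently bowed stalk
rising 50-110 mm above the canopy surface, topped by a narrow bud, with
two leaves diverging from the bud-leaf junction.  Shoot-tip geometry is
drawn uniformly from the measured field ranges (shoot length 27.5-30.2 mm,
stalk diameter 1.1-2.3 mm, pickable region 11.2-15.3 mm, leaf angle
45.6-54.2 deg) and consecutive tips are spaced 50-80 mm apart along the
row.

World coordinates are millimetres with the origin at the top-left corner
of the shooting window: X increases along the row, Z increases downward.
The default window height equals the rig's shooting-area height
Hs = 196 mm so that, at the default 5 px/mm, the rendered image is
Ht = 980 px tall and matches the device calibration exactly.

Every scene carries its exact ground truth (stem polylines, tips, true
picking points 4 mm below each tip, leaf polygons, per-shoot boxes), so
the whole downstream pipeline is testable without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as _draw_polygon

from .pickpoint import DetectionBox

__all__ = [
    "ShootParams",
    "ShootRecord",
    "SceneTruth",
    "GeneratorConfig",
    "RenderConfig",
    "RenderedScene",
    "DEFAULT_RANGES",
    "sample_shoot_params",
    "true_pick_point",
    "build_scene",
    "render",
]

#: Uniform sampling ranges for shoot-tip geometry (all mm except the leaf
#: angle in degrees).  The first four intervals are field measurements of
#: one-bud-one-leaf shoots; tip height is the measured growth height above
#: the canopy surface; the curvature amplitude (lateral bow of the stalk)
#: is a generator-internal parameter with a moderate default range.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "shoot_length_mm": (27.5, 30.2),
    "stalk_diameter_mm": (1.1, 2.3),
    "pickable_region_mm": (11.2, 15.3),
    "leaf_angle_deg": (45.6, 54.2),
    "tip_height_mm": (50.0, 110.0),
    "curvature_amplitude_mm": (0.0, 3.0),
}


@dataclass(frozen=True)
class ShootParams:
    """Geometry of a single tea shoot tip.

    ``optimal_region_mm`` (the upper picking region above the pickable
    zone) is carried as an optional annotation only; no measured range is
    available for it.
    """

    shoot_length_mm: float
    stalk_diameter_mm: float
    pickable_region_mm: float
    leaf_angle_deg: float
    tip_height_mm: float
    curvature_amplitude_mm: float
    optimal_region_mm: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "shoot_length_mm",
            "stalk_diameter_mm",
            "pickable_region_mm",
            "leaf_angle_deg",
            "tip_height_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.curvature_amplitude_mm < 0:
            raise ValueError("curvature_amplitude_mm must be >= 0")


@dataclass
class ShootRecord:
    """Ground truth for one rendered shoot."""

    stem_polyline: np.ndarray          # (N, 2) of (X, Z) mm, tip -> base, Z increasing
    tip: np.ndarray                    # (X, Z) mm of the bud-leaf junction
    true_pick_point: np.ndarray        # (X, Z) mm, on the polyline
    leaf_polygons: list[np.ndarray]    # two (M, 2) polygons in mm
    bud_polygon: np.ndarray            # (3, 2) wedge above the junction, mm
    bbox_world: tuple[float, float, float, float]  # (x_min, z_min, x_max, z_max) mm
    params: ShootParams


@dataclass
class SceneTruth:
    """World-coordinate ground truth for one synthetic row."""

    shoots: list[ShootRecord]
    canopy_height: float               # Z of the canopy surface, mm
    world_window: tuple[float, float]  # (width, height) mm


@dataclass
class GeneratorConfig:
    """Scene-level generation parameters (all lengths in mm)."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    tip_spacing_mm: tuple[float, float] = (50.0, 80.0)
    canopy_z_mm: float = 160.0
    window_height_mm: float = 196.0
    world_width_mm: float | None = None   # None: sized to fit the shoots
    margin_mm: float = 25.0
    polyline_step_mm: float = 0.5
    pick_offset_mm: float = 4.0
    bud_length_mm: float = 7.0
    bud_base_halfwidth_mm: float = 0.5
    leaf_length_frac: float = 0.7         # leaf length as a fraction of shoot length
    leaf_halfwidth_mm: float = 2.5
    leaf_base_halfwidth_mm: float = 0.3   # petiole half-width at the junction


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_shoot_params(
    rng: np.random.Generator | int | None,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> ShootParams:
    """Draw one shoot's geometry uniformly from the configured ranges."""
    rng = _as_rng(rng)
    ranges = dict(DEFAULT_RANGES) if ranges is None else ranges
    values: dict[str, float] = {}
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"invalid range for {name}: min {lo} > max {hi}")
        if name != "curvature_amplitude_mm" and lo <= 0:
            raise ValueError(f"range for {name} must be strictly positive")
        values[name] = float(rng.uniform(lo, hi)) if lo < hi else float(lo)
    return ShootParams(**values)


def true_pick_point(stem_polyline: np.ndarray, offset_mm: float = 4.0) -> np.ndarray:
    """Point on the stem polyline exactly ``offset_mm`` below the tip.

    The drop is measured vertically (in Z); X is linearly interpolated
    between polyline vertices.  With ``offset_mm = 0`` the tip itself is
    returned.
    """
    poly = np.asarray(stem_polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 2:
        raise ValueError("stem_polyline must be an (N, 2) array with N >= 2")
    z = poly[:, 1]
    if np.any(np.diff(z) <= 0):
        raise ValueError("stem polyline Z must be strictly increasing from tip to base")
    if z[-1] - z[0] < offset_mm:
        raise ValueError(
            f"polyline vertical extent {z[-1] - z[0]:.2f} mm shorter than offset {offset_mm} mm"
        )
    z_target = z[0] + offset_mm
    x_target = float(np.interp(z_target, z, poly[:, 0]))
    return np.array([x_target, z_target])


def _leaf_polygon(
    tip: np.ndarray, side: int, params: ShootParams, config: GeneratorConfig
) -> np.ndarray:
    """Kite-shaped leaf attached at the junction, pointing down and outward.

    The leaf axis makes the leaf angle with the (vertical) stem axis; the
    blade widens from a narrow petiole at the junction to its half-width at
    45 % of the leaf length and tapers to a point at the far end.  The
    narrow attachment keeps the skeleton junction tight at the tip, which
    is what the top-to-bottom intersection scan relies on.
    """
    beta = np.deg2rad(params.leaf_angle_deg)
    length = config.leaf_length_frac * params.shoot_length_mm
    axis = np.array([side * np.sin(beta), np.cos(beta)])
    perp = np.array([-axis[1], axis[0]])
    base1 = tip + perp * config.leaf_base_halfwidth_mm
    base2 = tip - perp * config.leaf_base_halfwidth_mm
    mid1 = tip + axis * 0.45 * length + perp * config.leaf_halfwidth_mm
    mid2 = tip + axis * 0.45 * length - perp * config.leaf_halfwidth_mm
    far = tip + axis * length
    return np.vstack([base1, mid1, far, mid2, base2])


def _bud_polygon(tip: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Narrow upward-tapering bud sitting on the junction."""
    hw = config.bud_base_halfwidth_mm
    top = tip - np.array([0.0, config.bud_length_mm])
    return np.vstack([top, tip + np.array([hw, 0.0]), tip + np.array([-hw, 0.0])])


def build_scene(
    n_shoots: int,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> SceneTruth:
    """Generate the ground truth for a row of ``n_shoots`` tea shoots.

    Tips are placed left to right with uniform random spacing inside the
    configured interval; each stem is a single-bow quadratic curve from the
    tip down to the canopy surface, with the lateral bow bounded by the
    shoot's curvature amplitude and a random bow direction.
    """
    if n_shoots < 1:
        raise ValueError("n_shoots must be >= 1")
    config = config or GeneratorConfig()
    rng = _as_rng(rng)
    lo, hi = config.tip_spacing_mm

    spacings = rng.uniform(lo, hi, size=max(n_shoots - 1, 0))
    tip_xs = config.margin_mm + np.concatenate([[0.0], np.cumsum(spacings)])
    needed = tip_xs[-1] + config.margin_mm
    if config.world_width_mm is not None:
        if config.world_width_mm < config.margin_mm * 2 + (n_shoots - 1) * lo:
            raise ValueError(
                f"world window {config.world_width_mm} mm too small for "
                f"{n_shoots} shoots at minimum spacing {lo} mm"
            )
        if needed > config.world_width_mm:
            # Re-draw cannot exceed the window at minimum spacing; squeeze
            # the drawn spacings proportionally into the available width.
            scale = (config.world_width_mm - 2 * config.margin_mm) / (
                tip_xs[-1] - config.margin_mm
            )
            tip_xs = config.margin_mm + (tip_xs - config.margin_mm) * scale
        width = config.world_width_mm
    else:
        width = needed

    shoots: list[ShootRecord] = []
    for x_tip in tip_xs:
        params = sample_shoot_params(rng, config.ranges)
        tip_z = config.canopy_z_mm - params.tip_height_mm
        if tip_z < 0:
            raise ValueError(
                "tip above the shooting window: reduce tip height range or lower the canopy"
            )
        bow_sign = 1 if rng.random() < 0.5 else -1
        n_steps = max(int(np.ceil(params.tip_height_mm / config.polyline_step_mm)), 2)
        zs = np.linspace(tip_z, config.canopy_z_mm, n_steps + 1)
        frac = (zs - tip_z) / (config.canopy_z_mm - tip_z)
        xs = x_tip + bow_sign * params.curvature_amplitude_mm * frac**2
        polyline = np.column_stack([xs, zs])
        tip = np.array([x_tip, tip_z])
        pick = true_pick_point(polyline, config.pick_offset_mm)
        leaves = [
            _leaf_polygon(tip, +1, params, config),
            _leaf_polygon(tip, -1, params, config),
        ]
        bud = _bud_polygon(tip, config)
        pieces = np.vstack(
            [polyline + [params.stalk_diameter_mm / 2, 0],
             polyline - [params.stalk_diameter_mm / 2, 0],
             bud, *leaves]
        )
        bbox = (
            float(pieces[:, 0].min()), float(pieces[:, 1].min()),
            float(pieces[:, 0].max()), float(pieces[:, 1].max()),
        )
        shoots.append(
            ShootRecord(
                stem_polyline=polyline,
                tip=tip,
                true_pick_point=pick,
                leaf_polygons=leaves,
                bud_polygon=bud,
                bbox_world=bbox,
                params=params,
            )
        )
    return SceneTruth(
        shoots=shoots,
        canopy_height=config.canopy_z_mm,
        world_window=(float(width), config.window_height_mm),
    )


@dataclass
class RenderConfig:
    """Rasterization parameters."""

    px_per_mm: float = 5.0
    fg_level: int = 255
    bg_level: int = 0
    noise_sigma: float = 0.0   # additive Gaussian noise, fraction of full scale
    box_margin_px: int = 2


@dataclass
class RenderedScene:
    """8-bit grayscale raster of a scene plus per-shoot pixel boxes."""

    image: np.ndarray
    px_per_mm: float
    boxes: list[DetectionBox]

    @property
    def image_height_Ht(self) -> int:
        return self.image.shape[0]


def _fill(layer: np.ndarray, poly_mm: np.ndarray, ppm: float) -> None:
    """Rasterize a world-coordinate polygon into a boolean layer.

    Pixel centers sit at world coordinates ``(index + 0.5) / px_per_mm``,
    so world position v maps to index coordinate ``v * ppm - 0.5``.
    """
    rr, cc = _draw_polygon(
        poly_mm[:, 1] * ppm - 0.5, poly_mm[:, 0] * ppm - 0.5, shape=layer.shape
    )
    layer[rr, cc] = True


def render(
    truth: SceneTruth,
    config: RenderConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> RenderedScene:
    """Rasterize a scene into an 8-bit grayscale side-view image.

    Stems are drawn as thick curved bands of the stalk diameter, the bud as
    a narrow tapering wedge above the junction, and the leaves as kite
    polygons; the area above each shoot is blank.  Ground-truth pixel
    boxes are the per-shoot foreground extents (expanded by a small
    margin) and are unaffected by the optional additive noise.
    """
    config = config or RenderConfig()
    if config.px_per_mm < 2:
        raise ValueError("px_per_mm must be >= 2 so the thinnest stalk spans 2 px")
    ppm = config.px_per_mm
    width_mm, height_mm = truth.world_window
    shape = (int(round(height_mm * ppm)), int(round(width_mm * ppm)))
    combined = np.zeros(shape, dtype=bool)
    boxes: list[DetectionBox] = []
    for shoot in truth.shoots:
        layer = np.zeros(shape, dtype=bool)
        hw = shoot.params.stalk_diameter_mm / 2.0
        poly = shoot.stem_polyline
        stem_band = np.vstack([poly + [hw, 0.0], poly[::-1] - [hw, 0.0]])
        _fill(layer, stem_band, ppm)
        _fill(layer, shoot.bud_polygon, ppm)
        for leaf in shoot.leaf_polygons:
            _fill(layer, leaf, ppm)
        rows = np.nonzero(layer.any(axis=1))[0]
        cols = np.nonzero(layer.any(axis=0))[0]
        m = config.box_margin_px
        boxes.append(
            DetectionBox(
                class_id=0,
                x_min=int(max(cols[0] - m, 0)),
                z_min=int(max(rows[0] - m, 0)),
                x_max=int(min(cols[-1] + 1 + m, shape[1])),
                z_max=int(min(rows[-1] + 1 + m, shape[0])),
            )
        )
        combined |= layer
    image = np.where(combined, config.fg_level, config.bg_level).astype(float)
    if config.noise_sigma > 0:
        rng = _as_rng(rng)
        image = image + rng.normal(0.0, config.noise_sigma * 255.0, size=shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return RenderedScene(image=image, px_per_mm=ppm, boxes=boxes)
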