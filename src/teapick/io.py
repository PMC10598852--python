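"""Reading and writing the package's on-disk formats.

Images are 8-bit grayscale PNG; detection boxes use the plain-text YOLO
label format (one ``class x_center y_center width height`` line per box,
all values normalized to [0, 1]); ground truth and reports are JSON;
calibration/config files are YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .pickpoint import CameraCalibration, DetectionBox, PickPoint
from .scene import SceneTruth, ShootParams, ShootRecord

__all__ = [
    "read_image",
    "write_image",
    "read_yolo_labels",
    "write_yolo_labels",
    "write_truth",
    "read_truth",
    "read_calibration",
    "write_pick_points",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image as a 2-D uint8 array."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return np.asarray(img, dtype=np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_yolo_labels(
    path: str | Path, image_width: int, image_height: int
) -> list[DetectionBox]:
    """Parse a YOLO label file into pixel-coordinate boxes (half-open)."""
    boxes: list[DetectionBox] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"malformed YOLO label line: {line!r}")
        cls = int(parts[0])
        xc, zc, w, h = (float(v) for v in parts[1:5])
        conf = float(parts[5]) if len(parts) == 6 else None
        x_min = int(round((xc - w / 2) * image_width))
        x_max = int(round((xc + w / 2) * image_width))
        z_min = int(round((zc - h / 2) * image_height))
        z_max = int(round((zc + h / 2) * image_height))
        boxes.append(
            DetectionBox(
                class_id=cls,
                x_min=max(x_min, 0),
                z_min=max(z_min, 0),
                x_max=min(x_max, image_width),
                z_max=min(z_max, image_height),
                confidence=conf,
            )
        )
    return boxes


def write_yolo_labels(
    path: str | Path, boxes: list[DetectionBox], image_width: int, image_height: int
) -> None:
    """Write boxes as normalized YOLO label lines (6-decimal fixed format)."""
    lines = []
    for b in boxes:
        xc = (b.x_min + b.x_max) / 2.0 / image_width
        zc = (b.z_min + b.z_max) / 2.0 / image_height
        w = b.width / image_width
        h = b.height / image_height
        lines.append(f"{b.class_id} {xc:.6f} {zc:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _shoot_to_dict(shoot: ShootRecord) -> dict:
    return {
        "stem_polyline": np.asarray(shoot.stem_polyline).tolist(),
        "tip": np.asarray(shoot.tip).tolist(),
        "pick_point": np.asarray(shoot.true_pick_point).tolist(),
        "leaf_polygons": [np.asarray(p).tolist() for p in shoot.leaf_polygons],
        "bud_polygon": np.asarray(shoot.bud_polygon).tolist(),
        "bbox_world": list(shoot.bbox_world),
        "params": {
            k: v for k, v in shoot.params.__dict__.items() if v is not None
        },
    }


def write_truth(path: str | Path, truth: SceneTruth) -> None:
    payload = {
        "canopy_height_mm": truth.canopy_height,
        "world_window_mm": list(truth.world_window),
        "shoots": [_shoot_to_dict(s) for s in truth.shoots],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> SceneTruth:
    payload = json.loads(Path(path).read_text())
    shoots = []
    for s in payload["shoots"]:
        shoots.append(
            ShootRecord(
                stem_polyline=np.asarray(s["stem_polyline"], dtype=float),
                tip=np.asarray(s["tip"], dtype=float),
                true_pick_point=np.asarray(s["pick_point"], dtype=float),
                leaf_polygons=[np.asarray(p, dtype=float) for p in s["leaf_polygons"]],
                bud_polygon=np.asarray(s["bud_polygon"], dtype=float),
                bbox_world=tuple(s["bbox_world"]),
                params=ShootParams(**s["params"]),
            )
        )
    return SceneTruth(
        shoots=shoots,
        canopy_height=payload["canopy_height_mm"],
        world_window=tuple(payload["world_window_mm"]),
    )


def read_calibration(path: str | Path, image_height: int | None = None) -> CameraCalibration:
    """Load a YAML/JSON calibration file.

    Recognized keys: ``Ht`` (px; defaults to the image height when given),
    ``Hs`` (mm, default 196), ``Hz`` (mm, default 212), ``x_scale``
    (mm/px, default Hs/Ht).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    ht = raw.get("Ht", image_height)
    if ht is None:
        raise ValueError("calibration needs Ht or an image to take the height from")
    return CameraCalibration(
        Ht=int(ht),
        Hs=float(raw.get("Hs", 196.0)),
        Hz=float(raw.get("Hz", 212.0)),
        x_scale=raw.get("x_scale"),
    )


def write_pick_points(out_dir: str | Path, points: list[PickPoint], skipped=()) -> None:
    """Write pick points as JSON and as a TSV (one row per box)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "points": [
            {
                "pixel": list(p.pixel),
                "world_mm": list(p.world),
                "intersection_pixel": list(p.intersection_px),
                "intersection_world_mm": list(p.intersection_world),
                "box": [p.source_box.x_min, p.source_box.z_min,
                        p.source_box.x_max, p.source_box.z_max],
                "flags": p.flags,
            }
            for p in points
        ],
        "skipped": [
            {"box": [b.x_min, b.z_min, b.x_max, b.z_max], "reason": reason}
            for b, reason in skipped
        ],
    }
    (out_dir / "pickpoints.json").write_text(json.dumps(payload, indent=1))
    rows = ["box_id\tXt\tZt\tXs_mm\tZs_mm\tflags"]
    for i, p in enumerate(points):
        rows.append(
            f"{i}\t{p.pixel[0]:.2f}\t{p.pixel[1]:.2f}"
            f"\t{p.world[0]:.3f}\t{p.world[1]:.3f}\t{','.join(p.flags) or '-'}"
        )
    (out_dir / "pickpoints.tsv").write_text("\n".join(rows) + "\n")
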