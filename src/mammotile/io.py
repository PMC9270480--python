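"""Readers and writers for the package's external formats.

Formats
-------
- Images: 16-bit single-channel PNG or TIFF (chosen by extension).
- Ground truth CSV: ``image_id,x_min,y_min,x_max,y_max,size_mm``.
- Predictions CSV: ``image_id,scale,x_min,y_min,x_max,y_max,score``
  (full-resolution frame).
- COCO-style JSON: ``bbox`` as ``[x, y, width, height]``; conversion to
  corner boxes is lossless in float.
- FROC outputs: points CSV (``threshold,fpi,sensitivity``) and a summary
  JSON with sensitivity at the configured FPI operating points.

Malformed rows are rejected with their line number and the offending
field, not silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import GeometryError, InputError
from .evaluate import FROCCurve
from .geometry import FULLRES, Box, Detection, Frame

__all__ = [
    "read_image",
    "write_image",
    "box_to_coco",
    "coco_to_box",
    "read_gt_csv",
    "write_gt_csv",
    "read_predictions_csv",
    "write_predictions_csv",
    "read_gt_coco",
    "write_gt_coco",
    "write_froc",
]

GT_COLUMNS = ["image_id", "x_min", "y_min", "x_max", "y_max", "size_mm"]
PRED_COLUMNS = ["image_id", "scale", "x_min", "y_min", "x_max", "y_max", "score"]


# ---------------------------------------------------------------- images


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


# ---------------------------------------------------------------- boxes


def box_to_coco(box: Box) -> list[float]:
    """Corner box -> COCO ``[x, y, width, height]`` (lossless)."""
    return [box.x_min, box.y_min, box.width, box.height]


def coco_to_box(bbox: Sequence[float]) -> Box:
    """COCO ``[x, y, width, height]`` -> corner box (exact inverse)."""
    x, y, w, h = bbox
    return Box(x, y, x + w, y + h)


def _row_box(row: pd.Series, line: int) -> Box:
    try:
        return Box(
            float(row["x_min"]),
            float(row["y_min"]),
            float(row["x_max"]),
            float(row["y_max"]),
        )
    except (ValueError, TypeError, GeometryError) as exc:
        raise InputError(f"line {line}: invalid box ({exc})") from exc


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{what} is missing columns {missing}")


# ---------------------------------------------------------------- GT CSV


def read_gt_csv(path: str | Path) -> dict[str, list[tuple[Box, float]]]:
    """Read ground truth into ``image_id -> [(box, size_mm), ...]``."""
    df = pd.read_csv(path)
    _require_columns(df, GT_COLUMNS[:5], f"GT table {path}")
    out: dict[str, list[tuple[Box, float]]] = {}
    for i, row in df.iterrows():
        box = _row_box(row, i + 2)  # +1 header, +1 one-based
        size = float(row["size_mm"]) if "size_mm" in df.columns else float("nan")
        out.setdefault(str(row["image_id"]), []).append((box, size))
    return out


def write_gt_csv(
    path: str | Path, gts: Mapping[str, Sequence[tuple[Box, float]]]
) -> None:
    rows = [
        {
            "image_id": image_id,
            "x_min": b.x_min,
            "y_min": b.y_min,
            "x_max": b.x_max,
            "y_max": b.y_max,
            "size_mm": size,
        }
        for image_id, items in gts.items()
        for b, size in items
    ]
    pd.DataFrame(rows, columns=GT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------- predictions CSV


def read_predictions_csv(path: str | Path) -> dict[str, list[Detection]]:
    """Read predictions into ``image_id -> [Detection, ...]``.

    Scores outside [0, 1] or degenerate boxes are rejected with their line
    number.
    """
    df = pd.read_csv(path)
    _require_columns(
        df, ["image_id", "x_min", "y_min", "x_max", "y_max", "score"], f"predictions {path}"
    )
    out: dict[str, list[Detection]] = {}
    for i, row in df.iterrows():
        line = i + 2
        box = _row_box(row, line)
        score = float(row["score"])
        if not 0.0 <= score <= 1.0:
            raise InputError(f"line {line}: score {score} outside [0, 1]")
        scale = float(row["scale"]) if "scale" in df.columns else 1.0
        frame = Frame(scale=scale) if scale != 1.0 else FULLRES
        out.setdefault(str(row["image_id"]), []).append(
            Detection(box=box, score=score, frame=frame)
        )
    return out


def write_predictions_csv(
    path: str | Path, preds: Mapping[str, Sequence[Detection]]
) -> None:
    rows = [
        {
            "image_id": image_id,
            "scale": d.frame.scale,
            "x_min": d.box.x_min,
            "y_min": d.box.y_min,
            "x_max": d.box.x_max,
            "y_max": d.box.y_max,
            "score": d.score,
        }
        for image_id, dets in preds.items()
        for d in dets
    ]
    pd.DataFrame(rows, columns=PRED_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------- COCO JSON


def write_gt_coco(
    path: str | Path,
    gts: Mapping[str, Sequence[tuple[Box, float]]],
    image_shapes: Mapping[str, tuple[int, int]] | None = None,
) -> None:
    """Write ground truth as COCO-style JSON with one 'lesion' category."""
    image_ids = {name: i + 1 for i, name in enumerate(gts)}
    images = []
    for name, idx in image_ids.items():
        entry = {"id": idx, "file_name": name}
        if image_shapes and name in image_shapes:
            h, w = image_shapes[name]
            entry.update({"height": int(h), "width": int(w)})
        images.append(entry)
    annotations = []
    ann_id = 1
    for name, items in gts.items():
        for box, size in items:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": image_ids[name],
                    "category_id": 1,
                    "bbox": box_to_coco(box),
                    "area": box.area,
                    "iscrowd": 0,
                    "size_mm": size,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "lesion"}],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_gt_coco(path: str | Path) -> dict[str, list[tuple[Box, float]]]:
    doc = json.loads(Path(path).read_text())
    try:
        names = {img["id"]: img["file_name"] for img in doc["images"]}
        out: dict[str, list[tuple[Box, float]]] = {n: [] for n in names.values()}
        for ann in doc["annotations"]:
            box = coco_to_box(ann["bbox"])
            out[names[ann["image_id"]]].append((box, float(ann.get("size_mm", "nan"))))
    except (KeyError, TypeError) as exc:
        raise InputError(f"malformed COCO file {path}: {exc}") from exc
    return out


# ---------------------------------------------------------------- FROC


def write_froc(
    curve: FROCCurve,
    points_csv: str | Path,
    summary_json: str | Path | None = None,
    fpi_list: Sequence[float] = (0.1, 0.15, 0.2, 0.3),
) -> None:
    curve.to_dataframe().to_csv(points_csv, index=False)
    if summary_json is not None:
        Path(summary_json).write_text(json.dumps(curve.summary(fpi_list), indent=2))
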