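"""Independent reference implementations used to check the package.

These deliberately avoid the package's own primitives where possible
(shapely for overlap areas, exhaustive loops instead of sweeps) so that
agreement is a genuine dual-route check.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import box as shapely_box

from mammotile.geometry import Box, Detection


def iou_shapely(a: Box, b: Box) -> float:
    pa = shapely_box(a.x_min, a.y_min, a.x_max, a.y_max)
    pb = shapely_box(b.x_min, b.y_min, b.x_max, b.y_max)
    union = pa.union(pb).area
    return pa.intersection(pb).area / union if union else 0.0


def nms_reference(detections, iou_threshold):
    """O(n^2) greedy NMS using shapely areas and explicit removal."""
    remaining = sorted(
        enumerate(detections), key=lambda t: (-t[1].score, -t[1].box.area, t[0])
    )
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best[1])
        remaining = [
            t for t in remaining if iou_shapely(best[1].box, t[1].box) <= iou_threshold
        ]
    return kept


def wbf_reference(per_source, iou_threshold, n_sources, rescale="clipped"):
    """Straightforward WBF re-implementation on plain tuples."""
    flat = [d for src in per_source for d in src]
    order = sorted(
        enumerate(flat), key=lambda t: (-t[1].score, -t[1].box.area, t[0])
    )
    clusters: list[list[Detection]] = []
    fused_boxes: list[tuple[float, float, float, float]] = []

    def weighted_box(members):
        w = np.array([m.score for m in members])
        coords = np.array([m.box.as_tuple() for m in members])
        return tuple((coords * w[:, None]).sum(axis=0) / w.sum())

    for _, det in order:
        ious = [
            iou_shapely(det.box, Box(*fb)) if fb else 0.0 for fb in fused_boxes
        ]
        best = int(np.argmax(ious)) if ious else -1
        if best >= 0 and ious[best] > iou_threshold:
            clusters[best].append(det)
            fused_boxes[best] = weighted_box(clusters[best])
        else:
            clusters.append([det])
            fused_boxes.append(weighted_box([det]))

    out = []
    for members, fb in zip(clusters, fused_boxes):
        n = len(members)
        mean = sum(m.score for m in members) / n
        factor = min(n, n_sources) / n_sources if rescale == "clipped" else n / n_sources
        out.append((fb, min(1.0, mean * factor)))
    out.sort(key=lambda t: -t[1])
    return out


def center_in(pred: Box, gt: Box) -> bool:
    cx = (pred.x_min + pred.x_max) / 2
    cy = (pred.y_min + pred.y_max) / 2
    return gt.x_min <= cx < gt.x_max and gt.y_min <= cy < gt.y_max


def froc_reference(preds, gts):
    """Exhaustive FROC: independent matcher rerun at every threshold.

    Default conventions: duplicates on one GT are not FPs; one prediction
    may credit several GTs.
    """
    n_images = len(gts)
    n_gt = sum(len(v) for v in gts.values())
    scores = sorted({d.score for ds in preds.values() for d in ds}, reverse=True)
    points = []
    for thr in [math.inf] + scores:
        hit_gt = set()
        n_fp = 0
        for image_id, gt_boxes in gts.items():
            for det in preds.get(image_id, ()):
                if det.score < thr:
                    continue
                matched = [g for g, gt in enumerate(gt_boxes) if center_in(det.box, gt)]
                if matched:
                    hit_gt.update((image_id, g) for g in matched)
                else:
                    n_fp += 1
        points.append((thr, n_fp / n_images, len(hit_gt) / n_gt))
    return points


def coverage_bruteforce(shape, tiles) -> bool:
    """Paint every tile onto a canvas and check all pixels are covered."""
    canvas = np.zeros(shape, dtype=bool)
    for tile in tiles:
        x, y = tile.offset
        w, h = tile.size
        if x < 0 or y < 0 or x + w > shape[1] or y + h > shape[0]:
            return False
        canvas[y : y + h, x : x + w] = True
    return bool(canvas.all())
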