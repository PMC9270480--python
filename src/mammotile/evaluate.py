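"""FROC evaluation with the center-in-ground-truth hit criterion.

A prediction counts as detecting a lesion iff its box *center* lies inside
the ground-truth box — the standard mammography-CAD rule, deliberately not
an IoU criterion.  Sensitivity is plotted against false-positive marks per
image (FPI) by sweeping the score threshold over the unique prediction
scores, which yields the exact step curve with no binning artifacts.

Conventions (both switchable): duplicate predictions on one ground truth
are not false positives, and a single prediction whose center lies in
several ground-truth boxes credits all of them.  Images with no lesions
still count in FPI denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .geometry import Box, Detection, box_center

__all__ = [
    "FROCPoint",
    "FROCCurve",
    "MatchResult",
    "is_hit",
    "match_at_threshold",
    "froc",
    "sensitivity_at_fpi",
]

PredMap = Mapping[str, Sequence[Detection]]
GtMap = Mapping[str, Sequence[Box]]


def is_hit(pred: Box, gt: Box) -> bool:
    """True iff the center of ``pred`` falls inside ``gt`` (half-open)."""
    cx, cy = box_center(pred)
    return gt.x_min <= cx < gt.x_max and gt.y_min <= cy < gt.y_max


@dataclass(frozen=True)
class FROCPoint:
    threshold: float
    fpi: float
    sensitivity: float


@dataclass(frozen=True)
class FROCCurve:
    """Ordered (threshold, FPI, sensitivity) points, threshold decreasing."""

    points: tuple[FROCPoint, ...]
    n_images: int = 0
    n_gt: int = 0

    def __post_init__(self) -> None:
        pts = self.points
        for a, b in zip(pts, pts[1:]):
            if not a.threshold > b.threshold:
                raise InputError("FROC thresholds must be strictly decreasing")
            if b.fpi < a.fpi or b.sensitivity < a.sensitivity:
                raise InputError("FROC fpi/sensitivity must be non-decreasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.threshold, p.fpi, p.sensitivity) for p in self.points],
            columns=["threshold", "fpi", "sensitivity"],
        )

    def summary(self, fpi_list: Sequence[float] = (0.1, 0.15, 0.2, 0.3)) -> dict:
        return {
            "n_images": self.n_images,
            "n_gt": self.n_gt,
            "sensitivity_at_fpi": {
                str(t): sensitivity_at_fpi(self, t) for t in fpi_list
            },
        }


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching predictions to ground truth at one threshold.

    ``hits`` maps ``(image_id, gt_index)`` to the indices (within that
    image's prediction list) of every kept prediction whose center falls in
    that ground-truth box.  ``false_positives`` lists ``(image_id,
    pred_index)`` of kept predictions hitting no ground truth.
    """

    hits: dict[tuple[str, int], tuple[int, ...]]
    false_positives: tuple[tuple[str, int], ...]
    n_gt: int
    n_images: int

    @property
    def n_hit(self) -> int:
        return len(self.hits)

    @property
    def sensitivity(self) -> float:
        return self.n_hit / self.n_gt if self.n_gt else float("nan")

    @property
    def fpi(self) -> float:
        return len(self.false_positives) / self.n_images


def _check_ids(preds: PredMap, gts: GtMap) -> None:
    unknown = set(preds) - set(gts)
    if unknown:
        raise InputError(
            f"prediction image ids absent from ground truth: {sorted(unknown)[:5]}"
        )


def match_at_threshold(
    preds: PredMap,
    gts: GtMap,
    threshold: float,
    *,
    duplicates_are_fp: bool = False,
    credit_multiple_gt: bool = True,
) -> MatchResult:
    """Match predictions scoring ``>= threshold`` to ground-truth boxes.

    A ground truth is detected when at least one kept prediction hits it;
    extra predictions on an already-hit ground truth are not false
    positives (unless ``duplicates_are_fp``), and one prediction may credit
    several ground truths (unless ``credit_multiple_gt`` is off, in which
    case it credits only the first it hits, in ground-truth order).
    """
    _check_ids(preds, gts)
    hits: dict[tuple[str, int], list[int]] = {}
    fps: list[tuple[str, int]] = []
    n_gt = sum(len(v) for v in gts.values())

    for image_id, gt_boxes in gts.items():
        for p_idx, det in enumerate(preds.get(image_id, ())):
            if det.score < threshold:
                continue
            hit_gts = [g for g, gt in enumerate(gt_boxes) if is_hit(det.box, gt)]
            if not credit_multiple_gt:
                hit_gts = hit_gts[:1]
            if not hit_gts:
                fps.append((image_id, p_idx))
                continue
            fresh = False
            for g_idx in hit_gts:
                key = (image_id, g_idx)
                if key not in hits:
                    fresh = True
                hits.setdefault(key, []).append(p_idx)
            if duplicates_are_fp and not fresh:
                fps.append((image_id, p_idx))

    return MatchResult(
        hits={k: tuple(v) for k, v in hits.items()},
        false_positives=tuple(fps),
        n_gt=n_gt,
        n_images=len(gts),
    )


def froc(
    preds: PredMap,
    gts: GtMap,
    *,
    duplicates_are_fp: bool = False,
    credit_multiple_gt: bool = True,
) -> FROCCurve:
    """Exact FROC curve: one point per unique prediction score plus +inf.

    ``gts`` must contain an entry for *every* evaluated image (an empty
    sequence for lesion-free images) — those images contribute to the FPI
    denominator.  Raises :class:`InputError` when there is no ground truth
    at all (sensitivity undefined).
    """
    _check_ids(preds, gts)
    if len(gts) < 1:
        raise InputError("froc requires at least one image")
    n_gt = sum(len(v) for v in gts.values())
    if n_gt == 0:
        raise InputError("froc requires at least one ground-truth box")

    n_images = len(gts)

    # Single descending-score sweep: each prediction's hit set is computed
    # once, then hits/FPs accumulate as the threshold drops past each
    # unique score.  Equivalent to rerunning match_at_threshold at every
    # unique score, but O(P*G + P log P) instead of O(T*P*G).
    entries = []  # (score, image_id, pred_index, hit gt keys)
    for image_id in gts:
        for p_idx, det in enumerate(preds.get(image_id, ())):
            hit_gts = [
                (image_id, g)
                for g, gt in enumerate(gts[image_id])
                if is_hit(det.box, gt)
            ]
            if not credit_multiple_gt:
                hit_gts = hit_gts[:1]
            entries.append((det.score, image_id, p_idx, hit_gts))
    entries.sort(key=lambda e: -e[0])

    points = [FROCPoint(threshold=math.inf, fpi=0.0, sensitivity=0.0)]
    hit_set: set[tuple[str, int]] = set()
    n_fp = 0
    i = 0
    while i < len(entries):
        thr = entries[i][0]
        while i < len(entries) and entries[i][0] == thr:
            _, _, _, hit_gts = entries[i]
            fresh = [k for k in hit_gts if k not in hit_set]
            if not hit_gts:
                n_fp += 1
            elif not fresh and duplicates_are_fp:
                n_fp += 1
            hit_set.update(hit_gts)
            i += 1
        points.append(
            FROCPoint(
                threshold=thr,
                fpi=n_fp / n_images,
                sensitivity=len(hit_set) / n_gt,
            )
        )
    return FROCCurve(points=tuple(points), n_images=n_images, n_gt=n_gt)


def sensitivity_at_fpi(curve: FROCCurve, target_fpi: float) -> float:
    """Maximum sensitivity among curve points with ``fpi <= target_fpi``.

    Conservative step convention — no interpolation; 0 when the curve has
    no point at or below the target FPI.
    """
    if target_fpi < 0:
        raise InputError("target_fpi must be >= 0")
    eligible = [p.sensitivity for p in curve.points if p.fpi <= target_fpi]
    return max(eligible) if eligible else 0.0
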