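"""Cross-scale combination of predictions: NMS, thresholded NMS, and WBF.

All three operate on detections already remapped into the full-resolution
frame.  NMS keeps a subset of its input; Weighted Box Fusion (WBF) instead
builds confidence-weighted average boxes from clusters of mutually
overlapping detections, down-weighting clusters supported by fewer than
the expected number of sources (one per pyramid scale by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigError
from .geometry import FULLRES, Box, Detection, iou

__all__ = ["FusionConfig", "nms", "wbf", "fuse_scales"]

_METHODS = ("wbf", "nms", "nms_threshold")
_DEFAULT_IOU = {"wbf": 0.55, "nms": 0.5, "nms_threshold": 0.5}


@dataclass(frozen=True)
class FusionConfig:
    """How per-scale prediction sets are combined.

    ``iou_threshold`` defaults to 0.55 for WBF and 0.5 for the NMS
    variants.  ``n_sources`` is the expected number of prediction sources
    (T, normally the number of scales); WBF rescales cluster scores by
    ``min(N, T) / T`` where N is cluster size, or by ``N / T`` when
    ``score_rescale='linear'``.  ``score_floor`` is the pre-filter used by
    the ``nms_threshold`` method.
    """

    method: str = "wbf"
    iou_threshold: float | None = None
    n_sources: int = 3
    score_floor: float = 0.0
    score_rescale: str = "clipped"  # 'clipped' -> min(N,T)/T, 'linear' -> N/T

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ConfigError(f"unknown fusion method {self.method!r}")
        thr = self.resolved_iou
        if not 0 < thr < 1:
            raise ConfigError(f"iou_threshold must be in (0, 1), got {thr}")
        if self.n_sources < 1:
            raise ConfigError("n_sources must be >= 1")
        if self.score_rescale not in ("clipped", "linear"):
            raise ConfigError(f"unknown score_rescale {self.score_rescale!r}")

    @property
    def resolved_iou(self) -> float:
        if self.iou_threshold is not None:
            return self.iou_threshold
        return _DEFAULT_IOU[self.method]


def _sort_key(indexed: tuple[int, Detection]):
    i, det = indexed
    # score desc, then larger area, then input order: deterministic ties
    return (-det.score, -det.box.area, i)


def nms(detections: Sequence[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Greedy non-maximum suppression.

    Repeatedly keeps the highest-scoring remaining detection and discards
    every other detection overlapping it with IoU strictly above the
    threshold.  Output is sorted by score descending.
    """
    order = sorted(enumerate(detections), key=_sort_key)
    kept: list[Detection] = []
    suppressed = [False] * len(order)
    for pos, (_, det) in enumerate(order):
        if suppressed[pos]:
            continue
        kept.append(det)
        for later in range(pos + 1, len(order)):
            if suppressed[later]:
                continue
            if iou(det.box, order[later][1].box) > iou_threshold:
                suppressed[later] = True
    return kept


class _Cluster:
    __slots__ = ("members", "fused_box")

    def __init__(self, det: Detection):
        self.members: list[Detection] = [det]
        self.fused_box = det.box

    def add(self, det: Detection) -> None:
        self.members.append(det)
        self._refuse()

    def _refuse(self) -> None:
        total = sum(m.score for m in self.members)
        self.fused_box = Box(
            sum(m.score * m.box.x_min for m in self.members) / total,
            sum(m.score * m.box.y_min for m in self.members) / total,
            sum(m.score * m.box.x_max for m in self.members) / total,
            sum(m.score * m.box.y_max for m in self.members) / total,
        )

    def fused(self, n_sources: int, rescale: str) -> Detection:
        n = len(self.members)
        mean_score = sum(m.score for m in self.members) / n
        if rescale == "clipped":
            factor = min(n, n_sources) / n_sources
        else:
            factor = n / n_sources
        return Detection(
            box=self.fused_box,
            score=min(1.0, mean_score * factor),
            frame=FULLRES,
        )


def wbf(
    per_source_detections: Sequence[Sequence[Detection]],
    config: FusionConfig | None = None,
) -> list[Detection]:
    """Weighted Box Fusion across prediction sources.

    Detections from all sources are processed in descending score order.
    Each is matched against the running list of clusters by IoU with the
    cluster's current fused box (best match above the threshold wins); a
    match joins that cluster, otherwise it seeds a new one.  A cluster's
    fused box is the score-weighted mean of its members' coordinates, and
    its score is the members' mean score rescaled by ``min(N, T) / T``
    (N = cluster size, T = expected sources).
    """
    if config is None:
        config = FusionConfig(method="wbf")
    thr = config.resolved_iou
    flat = [d for source in per_source_detections for d in source]
    order = [det for _, det in sorted(enumerate(flat), key=_sort_key)]

    clusters: list[_Cluster] = []
    for det in order:
        best_iou = 0.0
        best: _Cluster | None = None
        for cluster in clusters:
            v = iou(det.box, cluster.fused_box)
            if v > best_iou:
                best_iou = v
                best = cluster
        if best is not None and best_iou > thr:
            best.add(det)
        else:
            clusters.append(_Cluster(det))

    fused = [c.fused(config.n_sources, config.score_rescale) for c in clusters]
    return sorted(fused, key=lambda d: (-d.score, -d.box.area))


def fuse_scales(
    per_scale_detections: Sequence[Sequence[Detection]],
    config: FusionConfig,
) -> list[Detection]:
    """Dispatch cross-scale combination to the configured method.

    ``per_scale_detections`` holds one list per pyramid scale, all in the
    full-resolution frame.  The NMS variants pool the scales and suppress;
    WBF fuses.  Output is sorted by score descending.
    """
    if config.method == "wbf":
        return wbf(per_scale_detections, config)
    pooled = [d for source in per_scale_detections for d in source]
    if config.method == "nms_threshold":
        pooled = [d for d in pooled if d.score >= config.score_floor]
    elif config.method != "nms":
        raise ConfigError(f"unknown fusion method {config.method!r}")
    return nms(pooled, config.resolved_iou)
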