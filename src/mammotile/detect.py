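"""Pluggable detector contract plus a classical difference-of-Gaussians
reference detector.

A detector is any callable ``image -> list[Detection]`` that returns boxes
in the tile's own frame with scores in [0, 1], deterministically for a
fixed input.  The bundled reference detector responds only to blobs whose
scale falls inside its ``[sigma_min, sigma_max]`` band — the classical
analog of a network's bounded receptive field, which is what makes the
multi-scale pyramid matter: objects outside the band at one scale become
detectable at another.

:func:`run_scale` composes one pyramid level end to end: rescale, plan and
extract strip tiles, detect on each tile, remap detections to the
full-resolution frame, and suppress duplicates across overlapping tile
seams with NMS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter

from .errors import ConfigError
from .fuse import nms
from .geometry import FULLRES, Box, Detection, Frame, remap_to_fullres
from .pyramid import extract_tiles, plan_tiles, rescale

__all__ = [
    "Detector",
    "DetectorConfig",
    "DoGDetector",
    "ScriptedDetector",
    "load_tile_predictions_csv",
    "run_scale",
]


class Detector(Protocol):
    """Contract accepted by :func:`run_scale`."""

    def __call__(self, image: np.ndarray) -> list[Detection]: ...


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of the difference-of-Gaussians reference detector.

    The sigma band ``[sigma_min, sigma_max]`` (pixels) bounds the blob
    scales the detector can respond to.  Blob responses above
    ``response_threshold`` become detections; boxes have half-side
    ``box_radius_factor * sigma``.  Raw responses are squashed to [0, 1]
    scores by ``r / (r + score_softness)`` — monotone, so any
    ranking-based evaluation is unaffected by the exact constant.

    ``edge_ratio`` bounds the principal-curvature ratio at a peak:
    elongated, edge-like responses (e.g. along the breast skin line) are
    rejected, keeping only isotropic blob-like peaks.  ``inf`` disables
    the test.
    """

    sigma_min: float = 3.0
    sigma_max: float = 8.0
    n_sigma: int = 5
    response_threshold: float = 0.03
    box_radius_factor: float = 2.0
    score_softness: float = 0.05
    edge_ratio: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.sigma_min < self.sigma_max:
            raise ConfigError("need 0 < sigma_min < sigma_max")
        if self.n_sigma < 2:
            raise ConfigError("n_sigma must be >= 2")
        if self.response_threshold < 0:
            raise ConfigError("response_threshold must be >= 0")
        if self.box_radius_factor <= 0 or self.score_softness <= 0:
            raise ConfigError("box_radius_factor and score_softness must be > 0")

    def sigmas(self) -> np.ndarray:
        """Geometric sigma ladder with ``n_sigma + 1`` rungs."""
        return np.geomspace(self.sigma_min, self.sigma_max, self.n_sigma + 1)


def _is_blob_like(level: np.ndarray, y: int, x: int, edge_ratio: float) -> bool:
    """Hessian curvature-ratio test rejecting elongated (edge) responses.

    At a true isotropic blob peak the two principal curvatures of the DoG
    level are comparable; along an intensity edge one dominates.  Accepts
    the peak iff ``tr(H)^2 / det(H) < (r+1)^2 / r`` with ``r = edge_ratio``
    (and a negative-definite-consistent det > 0).
    """
    if not np.isfinite(edge_ratio):
        return True
    h, w = level.shape
    y0, y1 = max(y - 1, 0), min(y + 1, h - 1)
    x0, x1 = max(x - 1, 0), min(x + 1, w - 1)
    dxx = level[y, x1] - 2 * level[y, x] + level[y, x0]
    dyy = level[y1, x] - 2 * level[y, x] + level[y0, x]
    dxy = (level[y1, x1] - level[y1, x0] - level[y0, x1] + level[y0, x0]) / 4.0
    det = dxx * dyy - dxy * dxy
    if det <= 0:
        return False
    tr = dxx + dyy
    return tr * tr / det < (edge_ratio + 1.0) ** 2 / edge_ratio


def _normalize(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / np.iinfo(img.dtype).max
    return img.astype(np.float64)


@dataclass(frozen=True)
class DoGDetector:
    """Difference-of-Gaussians blob detector conforming to the contract."""

    config: DetectorConfig = DetectorConfig()

    def __call__(self, image: np.ndarray) -> list[Detection]:
        return detect(image, self.config)


def detect(image: np.ndarray, config: DetectorConfig) -> list[Detection]:
    """Run DoG blob detection on one tile.

    Builds a scale-normalized DoG stack over the sigma ladder, finds 3-D
    local maxima above the response threshold, rejects edge-like peaks,
    and emits one detection per surviving maximum with a box of half-side
    ``box_radius_factor * sigma``.  Returns boxes in the tile frame.
    """
    img = _normalize(image)
    if img.size == 0:
        return []
    h, w = img.shape
    sigmas = config.sigmas()
    smoothed = [gaussian_filter(img, s, mode="reflect") for s in sigmas]
    k = sigmas[1] / sigmas[0]
    stack = np.stack(
        [(smoothed[i] - smoothed[i + 1]) / (k - 1.0) for i in range(config.n_sigma)]
    )

    local_max = maximum_filter(stack, size=(3, 3, 3), mode="constant", cval=-np.inf)
    peaks = (stack == local_max) & (stack > config.response_threshold)
    levels, ys, xs = np.nonzero(peaks)

    detections: list[Detection] = []
    for lvl, y, x in zip(levels, ys, xs):
        if not _is_blob_like(stack[lvl], int(y), int(x), config.edge_ratio):
            continue
        sigma = float(sigmas[lvl])
        response = float(stack[lvl, y, x])
        r = config.box_radius_factor * sigma
        # boxes are NOT clipped to the tile: a blob sitting on a tile edge
        # must produce overlapping boxes in adjacent tiles so seam NMS can
        # merge them; clipping to the full image happens in run_scale
        score = response / (response + config.score_softness)
        detections.append(
            Detection(
                box=Box(x - r, y - r, x + r, y + r),
                score=min(1.0, score),
                frame=FULLRES,
            )
        )
    detections.sort(key=lambda d: -d.score)
    return detections


@dataclass(frozen=True)
class ScriptedDetector:
    """Adapter replaying externally produced per-tile predictions.

    ``script`` maps ``(scale, tile_offset_x, tile_offset_y)`` keys to the
    tile-frame detections to emit; tiles without an entry yield nothing.
    The active key is set by :func:`run_scale` before each tile via
    :meth:`for_tile`.  Used both to plug in real model outputs (read from
    CSV) and as the mock detector in contract tests.
    """

    script: Mapping[tuple[float, float, float], Sequence[Detection]]

    def for_tile(self, frame: Frame) -> "_BoundScriptedDetector":
        key = (frame.scale, frame.tile_offset[0], frame.tile_offset[1])
        return _BoundScriptedDetector(self.script.get(key, ()))


@dataclass(frozen=True)
class _BoundScriptedDetector:
    detections: Sequence[Detection]

    def __call__(self, image: np.ndarray) -> list[Detection]:
        return list(self.detections)


def load_tile_predictions_csv(path) -> ScriptedDetector:
    """Build a :class:`ScriptedDetector` from a per-tile predictions CSV.

    Expected columns: ``scale, tile_x, tile_y, x_min, y_min, x_max, y_max,
    score`` with box coordinates in the tile frame — the bridge for
    feeding predictions from an external (e.g. GPU-trained) model through
    the remapping/fusion/evaluation pipeline.
    """
    import pandas as pd

    from .errors import InputError

    df = pd.read_csv(path)
    required = ["scale", "tile_x", "tile_y", "x_min", "y_min", "x_max", "y_max", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"per-tile predictions {path} missing columns {missing}")
    script: dict[tuple[float, float, float], list[Detection]] = {}
    for i, row in df.iterrows():
        key = (float(row["scale"]), float(row["tile_x"]), float(row["tile_y"]))
        score = float(row["score"])
        if not 0.0 <= score <= 1.0:
            raise InputError(f"line {i + 2}: score {score} outside [0, 1]")
        script.setdefault(key, []).append(
            Detection(
                box=Box(
                    float(row["x_min"]), float(row["y_min"]),
                    float(row["x_max"]), float(row["y_max"]),
                ),
                score=score,
            )
        )
    return ScriptedDetector(script)


def _clip_box(box: Box, width: int, height: int) -> Box | None:
    """Clip a full-res box to image bounds; None if nothing remains."""
    x0, x1 = max(0.0, box.x_min), min(float(width), box.x_max)
    y0, y1 = max(0.0, box.y_min), min(float(height), box.y_max)
    if x1 - x0 < 1.0 or y1 - y0 < 1.0:
        return None
    return Box(x0, y0, x1, y1)


def run_scale(
    fullres_image: np.ndarray,
    scale: float,
    tile_len: int,
    detector: Detector | ScriptedDetector,
    *,
    seam_nms_iou: float | None = 0.5,
    scaled_image: np.ndarray | None = None,
) -> list[Detection]:
    """Detect at one pyramid scale and return full-resolution detections.

    Pipeline: rescale -> plan strip tiles -> extract -> detect per tile ->
    remap every box to the full-resolution frame -> suppress duplicates
    across overlapping tile seams with NMS at ``seam_nms_iou`` (pass
    ``None`` to disable, e.g. to feed raw per-tile output to fusion).

    Every returned detection's ``frame`` records the scale and tile offset
    it originated from.  ``scaled_image`` overrides the native rescale —
    the hook used by resolution/context ablations that substitute an
    upsampled low-resolution pyramid level (its dimensions must match
    ``rescale(fullres_image, scale)``).
    """
    if scaled_image is None:
        scaled_image = rescale(fullres_image, scale)
    plan = plan_tiles(scaled_image.shape[:2], tile_len, scale=scale)

    h, w = fullres_image.shape[:2]
    pooled: list[Detection] = []
    for tile_img, frame in extract_tiles(scaled_image, plan):
        if isinstance(detector, ScriptedDetector):
            dets = detector.for_tile(frame)(tile_img)
        else:
            dets = detector(tile_img)
        for det in dets:
            box = remap_to_fullres(det.box, frame)
            clipped = _clip_box(box, w, h)
            if clipped is None:
                continue
            pooled.append(Detection(box=clipped, score=det.score, frame=frame))
    if seam_nms_iou is not None:
        pooled = nms(pooled, seam_nms_iou)
    pooled.sort(key=lambda d: -d.score)
    return pooled
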