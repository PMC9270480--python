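"""End-to-end orchestration: preprocess -> per-scale tiled detection ->
cross-scale fusion -> FROC evaluation, with a replayable run manifest.

All randomness flows from the single seed in :class:`PipelineConfig`;
stages derive sub-seeds deterministically, so a rerun with the same config
and inputs is bit-identical.  Every artifact embeds the config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .detect import Detector, DetectorConfig, DoGDetector, run_scale
from .errors import ConfigError
from .evaluate import froc
from .fuse import FusionConfig, fuse_scales
from .geometry import Box, Detection
from .io import write_froc, write_predictions_csv
from .preprocess import crop_to_breast
from .pyramid import ScaleSpec

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to rerun one end-to-end inference pass."""

    scales: ScaleSpec = ScaleSpec()
    tile_len: int = 1024
    detector: DetectorConfig = DetectorConfig()
    fusion: FusionConfig = FusionConfig(method="wbf")
    eval_fpi_list: tuple[float, ...] = (0.1, 0.15, 0.2, 0.3)
    seed: int = 0
    apply_preprocess: bool = True
    preprocess_margin: int = 16
    seam_nms_iou: float | None = 0.5

    def __post_init__(self) -> None:
        if self.fusion.n_sources != len(self.scales):
            raise ConfigError(
                f"fusion.n_sources={self.fusion.n_sources} does not match "
                f"{len(self.scales)} scales; override explicitly if intended"
            )

    def to_dict(self) -> dict:
        return {
            "scales": list(self.scales.scales),
            "tile_len": self.tile_len,
            "detector": dict(self.detector.__dict__),
            "fusion": dict(self.fusion.__dict__),
            "eval_fpi_list": list(self.eval_fpi_list),
            "seed": self.seed,
            "apply_preprocess": self.apply_preprocess,
            "preprocess_margin": self.preprocess_margin,
            "seam_nms_iou": self.seam_nms_iou,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            scales=ScaleSpec(tuple(d.get("scales", (1.0, 0.5, 0.25)))),
            tile_len=int(d.get("tile_len", 1024)),
            detector=DetectorConfig(**d.get("detector", {})),
            fusion=FusionConfig(**d.get("fusion", {})),
            eval_fpi_list=tuple(d.get("eval_fpi_list", (0.1, 0.15, 0.2, 0.3))),
            seed=int(d.get("seed", 0)),
            apply_preprocess=bool(d.get("apply_preprocess", True)),
            preprocess_margin=int(d.get("preprocess_margin", 16)),
            seam_nms_iou=d.get("seam_nms_iou", 0.5),
        )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def predict_image(
    image: np.ndarray,
    config: PipelineConfig,
    detector: Detector | None = None,
) -> tuple[list[Detection], dict]:
    """Run the full multi-scale pipeline on one raw image.

    Returns fused detections in the raw-image frame plus per-stage counts.
    """
    if detector is None:
        detector = DoGDetector(config.detector)

    counts: dict = {}
    offset = (0, 0)
    work = image
    if config.apply_preprocess:
        work, record = crop_to_breast(image, margin=config.preprocess_margin)
        offset = record.offset
        counts["crop_offset"] = list(offset)
        counts["crop_size"] = list(record.cropped_size)

    per_scale: list[list[Detection]] = []
    for s in config.scales:
        dets = run_scale(
            work, s, config.tile_len, detector, seam_nms_iou=config.seam_nms_iou
        )
        counts[f"scale_{s:g}"] = len(dets)
        per_scale.append(dets)

    fused = fuse_scales(per_scale, config.fusion)
    counts["fused"] = len(fused)
    if offset != (0, 0):
        fused = [
            Detection(
                box=d.box.translate(offset[0], offset[1]),
                score=d.score,
                frame=d.frame,
            )
            for d in fused
        ]
    return fused, counts


def run_pipeline(
    config: PipelineConfig,
    images: Mapping[str, np.ndarray],
    gts: Mapping[str, Sequence[Box]] | None,
    out_dir: str | Path,
    detector: Detector | None = None,
) -> dict:
    """Execute the pipeline over a set of images and write all artifacts.

    Writes ``predictions.csv``, and — when ground truth is supplied —
    ``froc.csv`` plus ``summary.json``; always writes ``manifest.json``
    recording the config, its hash, package version, and per-stage counts.
    Returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    preds: dict[str, list[Detection]] = {}
    stage_counts: dict[str, dict] = {}
    for image_id in sorted(images):
        fused, counts = predict_image(images[image_id], config, detector)
        preds[image_id] = fused
        stage_counts[image_id] = counts

    write_predictions_csv(out_dir / "predictions.csv", preds)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_images": len(images),
        "stage_counts": stage_counts,
        "outputs": ["predictions.csv"],
    }

    if gts is not None:
        curve = froc(preds, gts)
        write_froc(
            curve,
            out_dir / "froc.csv",
            out_dir / "summary.json",
            fpi_list=config.eval_fpi_list,
        )
        manifest["n_gt"] = curve.n_gt
        manifest["sensitivity_at_fpi"] = curve.summary(config.eval_fpi_list)[
            "sensitivity_at_fpi"
        ]
        manifest["outputs"] += ["froc.csv", "summary.json"]

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
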