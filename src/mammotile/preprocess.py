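"""Breast-region foreground extraction and tight cropping.

Run before pyramid construction so that tiles cover only tissue, not empty
detector background.  The crop offset is recorded so boxes found on the
cropped image can be mapped back to the raw-image frame exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import PreprocessingError
from .geometry import Box

__all__ = ["CropRecord", "foreground_mask", "crop_to_breast"]


@dataclass(frozen=True)
class CropRecord:
    """Origin ``(x, y)`` and ``(width, height)`` of a crop within the raw image."""

    offset: tuple[int, int]
    cropped_size: tuple[int, int]

    def to_dict(self) -> dict:
        return {"offset": list(self.offset), "cropped_size": list(self.cropped_size)}

    @classmethod
    def from_dict(cls, d: dict) -> "CropRecord":
        return cls(tuple(d["offset"]), tuple(d["cropped_size"]))

    def to_raw_frame(self, box: Box) -> Box:
        """Map a box from the cropped-image frame back to the raw frame."""
        return box.translate(self.offset[0], self.offset[1])

    def from_raw_frame(self, box: Box) -> Box:
        """Map a raw-frame box into the cropped-image frame."""
        return box.translate(-self.offset[0], -self.offset[1])


def foreground_mask(
    image: np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """Binary breast mask: largest connected component above a threshold.

    The threshold defaults to Otsu's value on the intensity histogram; pass
    ``threshold`` to override with a fixed value.  Returns an all-False
    mask when nothing exceeds the threshold (e.g. a blank image) — callers
    decide how to treat that.
    """
    if image.size == 0:
        raise PreprocessingError("empty image")
    img = np.asarray(image)
    if threshold is None:
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=bool)
        threshold = threshold_otsu(img)
    binary = img > threshold
    if not binary.any():
        return np.zeros(img.shape, dtype=bool)
    labels = label(binary)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def crop_to_breast(
    image: np.ndarray,
    margin: int = 16,
    threshold: float | None = None,
) -> tuple[np.ndarray, CropRecord]:
    """Crop to the tight bounding box of the breast mask, plus a margin.

    The margin (default 16 px) is clipped to image bounds; use 0 for exact
    mask-bounding-box crops.  Raises :class:`PreprocessingError` when no
    foreground is found.
    """
    mask = foreground_mask(image, threshold=threshold)
    if not mask.any():
        raise PreprocessingError("no foreground found; cannot crop")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    y0 = max(0, rows[0] - margin)
    y1 = min(image.shape[0], rows[-1] + 1 + margin)
    x0 = max(0, cols[0] - margin)
    x1 = min(image.shape[1], cols[-1] + 1 + margin)
    record = CropRecord(offset=(int(x0), int(y0)), cropped_size=(int(x1 - x0), int(y1 - y0)))
    return image[y0:y1, x0:x1], record
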