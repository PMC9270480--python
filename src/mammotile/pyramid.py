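"""Scale-pyramid construction and systematic full-coverage strip tiling.

The pyramid holds rescaled copies of one image (default scales 1.0, 0.5,
0.25).  Each scaled image is cut into fixed-length strips along its long
axis, spanning the full short axis, such that every pixel belongs to at
least one strip: offsets advance by ``tile_len`` and the final strip is
anchored to the image edge, overlapping its predecessor when ``tile_len``
does not divide the long-axis extent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import ConfigError, GeometryError
from .geometry import Frame

__all__ = [
    "ScaleSpec",
    "Tile",
    "TilePlan",
    "rescale",
    "upsample",
    "plan_tiles",
    "extract_tiles",
]


@dataclass(frozen=True)
class ScaleSpec:
    """Ordered set of pyramid scales; must start at 1.0 and decrease."""

    scales: tuple[float, ...] = (1.0, 0.5, 0.25)

    def __post_init__(self) -> None:
        s = self.scales
        if not s:
            raise ConfigError("ScaleSpec requires at least one scale")
        if any(not (0 < v <= 1.0) for v in s):
            raise ConfigError(f"scales must lie in (0, 1], got {s}")
        if any(a <= b for a, b in zip(s, s[1:])):
            raise ConfigError(f"scales must be strictly decreasing, got {s}")
        if s[0] != 1.0:
            raise ConfigError(f"scales must contain 1.0 first, got {s}")

    def __iter__(self):
        return iter(self.scales)

    def __len__(self) -> int:
        return len(self.scales)


@dataclass(frozen=True)
class Tile:
    """One strip: origin ``(x, y)`` and size ``(width, height)`` in the scaled frame."""

    offset: tuple[int, int]
    size: tuple[int, int]


@dataclass(frozen=True)
class TilePlan:
    """Systematic strip layout for one scaled image.

    ``image_shape`` is the ``(height, width)`` of the scaled image the plan
    covers; tiles are emitted in deterministic sorted-offset order.
    """

    scale: float
    image_shape: tuple[int, int]
    tile_len: int
    tiles: tuple[Tile, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "image_shape": list(self.image_shape),
            "tile_len": self.tile_len,
            "tiles": [
                {"offset": list(t.offset), "size": list(t.size)} for t in self.tiles
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TilePlan":
        return cls(
            scale=float(d["scale"]),
            image_shape=tuple(d["image_shape"]),
            tile_len=int(d["tile_len"]),
            tiles=tuple(
                Tile(tuple(t["offset"]), tuple(t["size"])) for t in d["tiles"]
            ),
        )


def _output_shape(shape: tuple[int, int], factor: float) -> tuple[int, int]:
    return (int(round(shape[0] * factor)), int(round(shape[1] * factor)))


def rescale(image: np.ndarray, scale: float) -> np.ndarray:
    """Anti-aliased downscaling of an image by ``scale`` in (0, 1].

    Scale 1.0 returns the input array unchanged (identity, bit-exact).
    Integer input dtypes are preserved by rounding the resampled values.
    """
    if not 0 < scale <= 1.0:
        raise ConfigError(f"rescale requires scale in (0, 1], got {scale}")
    if scale == 1.0:
        return image
    out_shape = _output_shape(image.shape, scale)
    out = resize(
        image.astype(np.float64),
        out_shape,
        order=1,
        anti_aliasing=True,
        preserve_range=True,
        mode="reflect",
    )
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.round(out), info.min, info.max).astype(image.dtype)
    return out.astype(image.dtype)


def upsample(
    image: np.ndarray,
    factor: float,
    out_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Bilinear upsampling by ``factor >= 1``.

    ``out_shape`` overrides the rounded target dimensions, which is needed
    when an upsampled pyramid level must match the dimensions of the
    natively rescaled level exactly.
    """
    if factor < 1:
        raise ConfigError(f"upsample requires factor >= 1, got {factor}")
    if out_shape is None:
        out_shape = _output_shape(image.shape, factor)
    if tuple(out_shape) == image.shape:
        return image
    out = resize(
        image.astype(np.float64),
        out_shape,
        order=1,
        anti_aliasing=False,
        preserve_range=True,
        mode="reflect",
    )
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.round(out), info.min, info.max).astype(image.dtype)
    return out.astype(image.dtype)


def plan_tiles(
    scaled_shape: tuple[int, int], tile_len: int, scale: float = 1.0
) -> TilePlan:
    """Plan full-coverage strips of length ``tile_len`` along the long axis.

    Strips span the entire short axis.  Offsets along the long axis are
    ``0, tile_len, 2*tile_len, ...`` with the final strip anchored at
    ``L - tile_len`` so no pixel is left uncovered; if the long-axis extent
    ``L`` is at most ``tile_len`` a single strip of length ``L`` covers the
    image.  Tile count equals ``ceil(L / tile_len)``.
    """
    if tile_len <= 0:
        raise ConfigError(f"tile_len must be > 0, got {tile_len}")
    h, w = int(scaled_shape[0]), int(scaled_shape[1])
    if h <= 0 or w <= 0:
        raise GeometryError(f"empty image shape {scaled_shape}")
    long_axis = 0 if h >= w else 1  # 0 = rows/y, 1 = cols/x
    L = h if long_axis == 0 else w

    if L <= tile_len:
        starts = [0]
        length = L
    else:
        n = math.ceil(L / tile_len)
        starts = [i * tile_len for i in range(n - 1)] + [L - tile_len]
        length = tile_len

    tiles = []
    for s in starts:
        if long_axis == 0:
            tiles.append(Tile(offset=(0, s), size=(w, length)))
        else:
            tiles.append(Tile(offset=(s, 0), size=(length, h)))
    return TilePlan(scale=scale, image_shape=(h, w), tile_len=tile_len, tiles=tuple(tiles))


def extract_tiles(
    image: np.ndarray, plan: TilePlan
) -> list[tuple[np.ndarray, Frame]]:
    """Cut the planned strips out of ``image`` as exact sub-arrays.

    Each tile is paired with the :class:`Frame` carrying the plan's scale
    and the tile's offset, so detections made on the tile can be remapped
    to full resolution.
    """
    if image.shape[:2] != plan.image_shape:
        raise GeometryError(
            f"plan is for shape {plan.image_shape}, image has {image.shape[:2]}"
        )
    out = []
    for tile in plan.tiles:
        x, y = tile.offset
        w, h = tile.size
        if x + w > image.shape[1] or y + h > image.shape[0]:
            raise GeometryError(f"tile {tile} exceeds image bounds {image.shape}")
        sub = image[y : y + h, x : x + w]
        out.append((sub, Frame(scale=plan.scale, tile_offset=(float(x), float(y)))))
    return out
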