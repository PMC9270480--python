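"""Core box and coordinate-frame types shared by every stage of the pipeline.

Conventions
-----------
Boxes are axis-aligned rectangles in pixel units: 0-based, half-open
``[min, max)`` intervals on both axes, with y growing downward (raster
order).  Coordinates are floats throughout — remapping a box out of a
reduced-scale tile produces fractional pixel positions, and rounding is
deferred to rasterization.

A :class:`Frame` names the coordinate system a box lives in: the scale of
the resized image it was produced on, and the offset of the tile within
that scaled image.  The full-resolution frame is ``Frame(1.0, (0, 0))``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import GeometryError, InvalidFrameError

__all__ = [
    "Box",
    "Frame",
    "Detection",
    "FULLRES",
    "iou",
    "box_center",
    "remap_to_fullres",
    "remap_from_fullres",
]


@dataclass(frozen=True, slots=True)
class Box:
    """Axis-aligned rectangle ``[x_min, x_max) x [y_min, y_max)`` in pixels."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise GeometryError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)


@dataclass(frozen=True, slots=True)
class Frame:
    """Coordinate frame of a detection: image scale plus tile offset.

    ``tile_offset`` is ``(x, y)`` in pixels of the *scaled* image; a box in
    this frame maps to full resolution by adding the offset and dividing by
    ``scale``.
    """

    scale: float = 1.0
    tile_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise InvalidFrameError(f"frame scale must be > 0, got {self.scale}")
        if self.tile_offset[0] < 0 or self.tile_offset[1] < 0:
            raise InvalidFrameError(
                f"tile offset components must be >= 0, got {self.tile_offset}"
            )


FULLRES = Frame(1.0, (0.0, 0.0))


@dataclass(frozen=True, slots=True)
class Detection:
    """A scored box together with the frame that produced it.

    After :func:`remap_to_fullres` the box coordinates are full-resolution;
    ``frame`` is then retained as provenance (which scale / tile the
    detection came from).
    """

    box: Box
    score: float
    frame: Frame = FULLRES

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise GeometryError(f"score must be in [0, 1], got {self.score}")


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes, in ``[0, 1]``.

    Degenerate (empty) overlap returns 0.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def box_center(box: Box) -> tuple[float, float]:
    """Center ``(cx, cy)`` of a box."""
    return ((box.x_min + box.x_max) / 2.0, (box.y_min + box.y_max) / 2.0)


def remap_to_fullres(box: Box, frame: Frame) -> Box:
    """Map a box from a tile frame into the full-resolution image frame.

    Each coordinate ``c`` maps to ``(c + offset) / scale``, where ``offset``
    is the matching component of ``frame.tile_offset``.
    """
    ox, oy = frame.tile_offset
    s = frame.scale
    return Box(
        (box.x_min + ox) / s,
        (box.y_min + oy) / s,
        (box.x_max + ox) / s,
        (box.y_max + oy) / s,
    )


def remap_from_fullres(box: Box, frame: Frame) -> Box:
    """Exact inverse of :func:`remap_to_fullres`."""
    ox, oy = frame.tile_offset
    s = frame.scale
    return Box(
        box.x_min * s - ox,
        box.y_min * s - oy,
        box.x_max * s - ox,
        box.y_max * s - oy,
    )
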