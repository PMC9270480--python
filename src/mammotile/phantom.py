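"""Seeded synthetic mammography-like phantoms with exact ground-truth boxes.

A phantom is a 16-bit grayscale image holding a breast-shaped half-ellipse
flush with the left image edge on a dark background.  The breast interior
carries a stationary parenchyma-like texture (low-pass-filtered Gaussian
noise around mid-gray), into which bright, radially tapered lesion discs of
prescribed physical diameter are inserted.  Physical size in millimetres is
converted to pixels through the detector pixel spacing in micrometres.

Everything is driven by a single integer seed: the same spec always
produces a bit-identical image and identical ground-truth boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, GenerationError
from .geometry import Box

__all__ = [
    "PhantomSpec",
    "PhantomOutput",
    "mm_to_px",
    "generate_phantom",
    "generate_dataset",
]

_DTYPE = np.uint16
_MAX = float(np.iinfo(_DTYPE).max)

# breast interior intensity band, as fractions of the 16-bit dynamic range
_BG_LEVEL = 0.35
_TEXTURE_AMP = 0.02


def mm_to_px(size_mm: float, spacing_um: float) -> float:
    """Convert a physical size in millimetres to pixels.

    ``spacing_um`` is the pixel spacing in micrometres (e.g. 70 um/px), so
    the result is ``size_mm * 1000 / spacing_um``.
    """
    if size_mm <= 0 or spacing_um <= 0:
        raise ConfigError(
            f"sizes must be positive, got size={size_mm} mm, spacing={spacing_um} um"
        )
    return size_mm * 1000.0 / spacing_um


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic image.

    ``lesion_diameters`` are physical diameters in mm; ``pixel_spacing`` (um)
    links them to pixel extents.  ``lesion_contrast`` is the fraction of the
    16-bit dynamic range added at each lesion's center.

    ``n_distractors`` inserts benign-mass-like discs that are *not* part of
    the ground truth: lower-contrast blobs that give detectors a realistic,
    reproducible false-positive population (benign masses are the dominant
    false-positive source in mammography CAD).
    """

    height: int = 4096
    width: int = 3328
    pixel_spacing: float = 70.0
    lesion_diameters: tuple[float, ...] = ()
    lesion_contrast: float = 0.3
    background_texture_sigma: float = 12.0
    spiculation: bool = False
    n_distractors: int = 0
    distractor_contrast: float = 0.27
    distractor_diameter_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ConfigError("image dimensions must be positive")
        if self.pixel_spacing <= 0:
            raise ConfigError("pixel_spacing must be positive")
        if any(d <= 0 for d in self.lesion_diameters):
            raise ConfigError("lesion diameters must be positive")
        if not 0 < self.lesion_contrast <= 1:
            raise ConfigError("lesion_contrast must be in (0, 1]")
        if self.n_distractors < 0:
            raise ConfigError("n_distractors must be >= 0")
        if self.n_distractors and not (
            0 < self.distractor_contrast <= 1 and self.distractor_diameter_mm > 0
        ):
            raise ConfigError("invalid distractor parameters")
        if self.background_texture_sigma <= 0:
            raise ConfigError("background_texture_sigma must be positive")

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_diameters)


@dataclass(frozen=True)
class PhantomOutput:
    """A generated image plus its exact annotations.

    ``gt_boxes`` tightly bound each lesion's support disc, in the
    full-resolution image frame.  ``distractor_boxes`` bound the inserted
    benign distractors (not ground truth — hits on them count as false
    positives).  ``breast_mask`` is the generator's own foreground mask,
    kept for validation of downstream segmentation.
    """

    image: np.ndarray
    gt_boxes: tuple[Box, ...]
    lesion_sizes_mm: tuple[float, ...]
    breast_mask: np.ndarray
    distractor_boxes: tuple[Box, ...] = ()


def _breast_ellipse(
    rng: np.random.Generator, height: int, width: int
) -> tuple[float, float, float]:
    """Half-ellipse parameters (cy, rx, ry) flush with the left edge.

    The vertical semi-axis slightly exceeds the half-height so the breast
    spans the full image height (flush against the detector edge, as in
    FFDM); sized so the in-image area is a 40-70% fraction of the image.
    """
    ry = 0.5 * height * rng.uniform(1.0, 1.08)
    frac = rng.uniform(0.45, 0.62)
    rx = frac * height * width / ((np.pi / 2.0) * ry)
    rx = float(np.clip(rx, 0.35 * width, 0.98 * width))
    return height / 2.0, rx, ry


def _lesion_profile(radius_px: float) -> np.ndarray:
    """Raised-cosine tapered disc, unit amplitude at the center."""
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    dist = np.hypot(yy, xx)
    prof = 0.5 * (1.0 + np.cos(np.pi * np.minimum(dist / radius_px, 1.0)))
    prof[dist > radius_px] = 0.0
    return prof


def _draw_spiculations(
    canvas: np.ndarray,
    rng: np.random.Generator,
    cx: float,
    cy: float,
    radius_px: float,
    amplitude: float,
) -> None:
    """Add 4-8 thin radial line segments of length 1-2 lesion radii."""
    from skimage.draw import line

    h, w = canvas.shape
    n = int(rng.integers(4, 9))
    angles = rng.uniform(0, 2 * np.pi, size=n)
    for ang in angles:
        length = rng.uniform(1.0, 2.0) * radius_px
        r0 = 0.9 * radius_px
        x0 = int(round(cx + r0 * np.cos(ang)))
        y0 = int(round(cy + r0 * np.sin(ang)))
        x1 = int(round(cx + (r0 + length) * np.cos(ang)))
        y1 = int(round(cy + (r0 + length) * np.sin(ang)))
        rr, cc = line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[keep], cc[keep]] += amplitude * 0.5


def _place_lesions(
    rng: np.random.Generator,
    spec: PhantomSpec,
    cy: float,
    rx: float,
    ry: float,
    radii_px: list[float],
    n_lesions: int | None = None,
    max_retries: int = 1000,
) -> list[tuple[float, float]]:
    """Rejection-sample lesion centers inside the shrunken breast ellipse.

    Between ground-truth lesions (the first ``n_lesions`` entries) a
    minimum pairwise center distance of 3 lesion diameters (of the larger
    member) keeps annotations well separated; pairs involving a
    distractor only need non-overlap clearance of twice the summed radii.
    Raises :class:`GenerationError` when a center cannot be placed within
    ``max_retries`` draws.
    """
    if n_lesions is None:
        n_lesions = len(radii_px)
    margin = 4.0
    centers: list[tuple[float, float]] = []
    for i, r_px in enumerate(radii_px):
        # shrink by r*sqrt(2) so the tight bounding *box* corners stay
        # inside the ellipse, not just the disc itself
        t = r_px * np.sqrt(2.0) + margin
        ex = rx - t
        ey = ry - t
        if ex <= 0 or ey <= 0:
            raise GenerationError(
                f"lesion of radius {r_px:.1f} px does not fit in breast "
                f"(rx={rx:.0f}, ry={ry:.0f})"
            )
        y_lo = max(cy - ry, t)
        y_hi = min(cy + ry, 2 * cy - t)  # 2*cy = image height
        for _ in range(max_retries):
            x = rng.uniform(r_px + margin, rx)
            y = rng.uniform(y_lo, y_hi)
            if (x / ex) ** 2 + ((y - cy) / ey) ** 2 > 1.0:
                continue
            ok = True
            for j, (px_, py_) in enumerate(centers):
                if i < n_lesions and j < n_lesions:
                    min_dist = 3.0 * 2.0 * max(r_px, radii_px[j])
                else:
                    min_dist = 2.0 * (r_px + radii_px[j])
                if np.hypot(x - px_, y - py_) < min_dist:
                    ok = False
                    break
            if ok:
                centers.append((x, y))
                break
        else:
            raise GenerationError(
                f"could not place lesion {i} after {max_retries} retries"
            )
    return centers


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render one phantom image from its spec, deterministically.

    The background outside the breast is 0; inside, intensities sit in a
    mid-gray band with low-pass-filtered noise texture.  Each lesion is a
    radially decaying bright disc whose center intensity is raised by
    ``lesion_contrast`` times the dynamic range; the ground-truth box is
    the tight bounding square of the disc.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    cy, rx, ry = _breast_ellipse(rng, h, w)
    yy, xx = np.ogrid[0:h, 0:w]
    mask = (xx / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0

    noise = rng.standard_normal((h, w))
    tex = gaussian_filter(noise, spec.background_texture_sigma)
    std = tex.std()
    if std > 0:
        tex /= std

    canvas = np.zeros((h, w), dtype=np.float64)
    canvas[mask] = _BG_LEVEL * _MAX + _TEXTURE_AMP * _MAX * tex[mask]

    lesion_radii = [mm_to_px(d, spec.pixel_spacing) / 2.0 for d in spec.lesion_diameters]
    distractor_radii = [
        mm_to_px(spec.distractor_diameter_mm, spec.pixel_spacing) / 2.0
    ] * spec.n_distractors
    radii_px = lesion_radii + distractor_radii
    if any(2 * r >= min(h, w) for r in radii_px):
        raise GenerationError("lesion larger than the image")

    centers = (
        _place_lesions(rng, spec, cy, rx, ry, radii_px, n_lesions=len(lesion_radii))
        if radii_px
        else []
    )

    def draw_disc(x: float, y: float, r_px: float, amplitude: float) -> Box:
        prof = _lesion_profile(r_px)
        r = prof.shape[0] // 2
        ix, iy = int(round(x)), int(round(y))
        y0, y1 = iy - r, iy + r + 1
        x0, x1 = ix - r, ix + r + 1
        # placement guarantees the window is interior, but clip defensively
        sy0, sx0 = max(0, -y0), max(0, -x0)
        y0, x0 = max(0, y0), max(0, x0)
        y1, x1 = min(h, y1), min(w, x1)
        canvas[y0:y1, x0:x1] += amplitude * prof[
            sy0 : sy0 + (y1 - y0), sx0 : sx0 + (x1 - x0)
        ]
        return Box(ix - r_px, iy - r_px, ix + r_px, iy + r_px)

    n_lesions = len(lesion_radii)
    gt_boxes = []
    amplitude = spec.lesion_contrast * _MAX
    for (x, y), r_px in zip(centers[:n_lesions], lesion_radii):
        gt_boxes.append(draw_disc(x, y, r_px, amplitude))
        if spec.spiculation:
            _draw_spiculations(canvas, rng, x, y, r_px, amplitude)

    distractor_boxes = []
    d_amplitude = spec.distractor_contrast * _MAX
    for (x, y), r_px in zip(centers[n_lesions:], distractor_radii):
        distractor_boxes.append(draw_disc(x, y, r_px, d_amplitude))

    image = np.clip(np.round(canvas), 0, _MAX).astype(_DTYPE)
    return PhantomOutput(
        image=image,
        gt_boxes=tuple(gt_boxes),
        lesion_sizes_mm=tuple(spec.lesion_diameters),
        breast_mask=mask,
        distractor_boxes=tuple(distractor_boxes),
    )


def generate_dataset(
    n_images: int,
    size_mix_mm: tuple[float, ...],
    seed: int,
    *,
    n_lesions_range: tuple[int, int] = (1, 2),
    base_spec: PhantomSpec | None = None,
) -> tuple[list[str], list[PhantomOutput], pd.DataFrame]:
    """Generate a seeded multi-image phantom set plus its annotation table.

    Per-image seeds derive deterministically from the master seed, so the
    same call always yields the identical dataset.  ``size_mix_mm`` is the
    pool of lesion diameters sampled (uniformly with replacement) for each
    lesion; ``n_lesions_range`` bounds the per-image lesion count
    (inclusive).

    Returns ``(image_ids, outputs, gt_table)`` where the table has columns
    ``image_id, x_min, y_min, x_max, y_max, size_mm`` — one row per lesion.
    Images without lesions still contribute an id (evaluation counts them
    in false-positive denominators).
    """
    if n_images <= 0:
        raise ConfigError("n_images must be positive")
    if base_spec is None:
        base_spec = PhantomSpec()

    master = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_images)]

    ids: list[str] = []
    outputs: list[PhantomOutput] = []
    rows: list[dict] = []
    lo, hi = n_lesions_range
    for i in range(n_images):
        image_id = f"phantom_{i:04d}"
        n_lesions = int(master.integers(lo, hi + 1)) if size_mix_mm else 0
        diameters = tuple(
            float(master.choice(np.asarray(size_mix_mm, dtype=float)))
            for _ in range(n_lesions)
        )
        # lesion mixes with several large diameters can make the 3-diameter
        # spacing rule infeasible in a small breast; deterministically drop
        # the largest lesion and retry rather than failing the whole set
        while True:
            spec = replace(base_spec, lesion_diameters=diameters, seed=child_seeds[i])
            try:
                out = generate_phantom(spec)
                break
            except GenerationError:
                if not diameters:
                    raise
                drop = diameters.index(max(diameters))
                diameters = diameters[:drop] + diameters[drop + 1 :]
        ids.append(image_id)
        outputs.append(out)
        for box, size in zip(out.gt_boxes, out.lesion_sizes_mm):
            rows.append(
                {
                    "image_id": image_id,
                    "x_min": box.x_min,
                    "y_min": box.y_min,
                    "x_max": box.x_max,
                    "y_max": box.y_max,
                    "size_mm": size,
                }
            )
    table = pd.DataFrame(
        rows, columns=["image_id", "x_min", "y_min", "x_max", "y_max", "size_mm"]
    )
    return ids, outputs, table
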