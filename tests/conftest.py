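from __future__ import annotations

import numpy as np
import pytest

from mammotile.geometry import Box, Detection
from mammotile.phantom import PhantomSpec, generate_phantom

# scaled-down phantom geometry shared by the heavier tests: 1/16 the area
# of the full-size default, with proportionally coarser pixel spacing so
# physical lesion sizes keep the same pixel extent ratios
SMALL_KW = dict(
    height=1024,
    width=832,
    pixel_spacing=280.0,
    lesion_contrast=0.35,
    background_texture_sigma=4.0,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One cached small phantom with a lesion of each size regime."""
    spec = PhantomSpec(lesion_diameters=(5.0, 20.0), seed=7, **SMALL_KW)
    return generate_phantom(spec)


def random_box(rng: np.random.Generator, lo=0.0, hi=100.0) -> Box:
    x0, x1 = np.sort(rng.uniform(lo, hi, 2))
    y0, y1 = np.sort(rng.uniform(lo, hi, 2))
    return Box(x0, y0, x1 + 1e-3, y1 + 1e-3)


def random_detections(rng: np.random.Generator, n: int, extent=100.0) -> list[Detection]:
    out = []
    for _ in range(n):
        cx, cy = rng.uniform(10, extent - 10, 2)
        w, h = rng.uniform(2, 30, 2)
        out.append(
            Detection(
                box=Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
                score=float(rng.uniform(0.01, 1.0)),
            )
        )
    return out
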