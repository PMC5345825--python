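"""Shared fixtures: canonical shapes and small rendered scenes."""

from __future__ import annotations

import numpy as np
import pytest

from feulgen import optics, synthetic


def random_blob(rng: np.random.Generator, size: int = 40) -> np.ndarray:
    """A random connected blob mask built from a few overlapping discs."""
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    cx0, cy0 = size // 2, size // 2
    r0 = rng.integers(4, 9)
    mask |= (xx - cx0) ** 2 + (yy - cy0) ** 2 <= r0**2
    for _ in range(rng.integers(1, 4)):
        dx, dy = rng.integers(-r0, r0 + 1, size=2)
        r = rng.integers(3, 8)
        cx, cy = np.clip(cx0 + dx, r + 1, size - r - 2), np.clip(cy0 + dy, r + 1, size - r - 2)
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return mask


@pytest.fixture
def square_mask() -> np.ndarray:
    """10x10 filled square with a 2-pixel margin."""
    mask = np.zeros((14, 14), dtype=bool)
    mask[2:12, 2:12] = True
    return mask


@pytest.fixture
def disc_mask() -> np.ndarray:
    """Digitised disc of radius 20."""
    yy, xx = np.mgrid[0:50, 0:50]
    return (xx - 24) ** 2 + (yy - 24) ** 2 <= 400


@pytest.fixture(scope="session")
def normal_scene():
    """Rendered noise-free normal-stage scene with its OD plane."""
    spec = synthetic.stage_preset("normal", 25, seed=11)
    rgb, blank, truth = synthetic.render_scene(spec)
    green, od = optics.od_from_raw(rgb, blank)
    return spec, rgb, blank, truth, green, od
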