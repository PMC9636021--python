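import math

import numpy as np
import pytest


def rasterize_disk(radius: int, pad: int = 6) -> np.ndarray:
    n = 2 * radius + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2.0
    return ((yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2).astype(int)


def rasterize_rotated_rect(
    angle_deg: float, half_len: float, half_w: float, shape=(200, 200)
):
    """Axis-unaligned rectangle; returns (labels, u, v, center) where u/v are
    the along/across unit vectors in (y, x) order."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    c = np.array([shape[0] / 2.0, shape[1] / 2.0])
    a = math.radians(angle_deg)
    u = np.array([math.cos(a), math.sin(a)])
    v = np.array([-math.sin(a), math.cos(a)])
    dy, dx = yy - c[0], xx - c[1]
    lu = dy * u[0] + dx * u[1]
    lv = dy * v[0] + dx * v[1]
    mask = (np.abs(lu) <= half_len) & (np.abs(lv) <= half_w)
    return mask.astype(int), u, v, c


def rasterize_rotated_capsule(
    angle_deg: float, half_len: float, half_w: float, shape=(140, 140)
) -> np.ndarray:
    """Capsule (rod) at an arbitrary orientation: distance-to-segment raster."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    c = np.array([shape[0] / 2.0, shape[1] / 2.0])
    a = math.radians(angle_deg)
    u = np.array([math.cos(a), math.sin(a)])
    v = np.array([-math.sin(a), math.cos(a)])
    dy, dx = yy - c[0], xx - c[1]
    lu = dy * u[0] + dx * u[1]
    lv = dy * v[0] + dx * v[1]
    lu_c = np.clip(np.abs(lu) - (half_len - half_w), 0.0, None)
    return ((lu_c ** 2 + lv ** 2) <= half_w ** 2).astype(int)


@pytest.fixture
def disk100() -> np.ndarray:
    return rasterize_disk(100)


@pytest.fixture
def capsule() -> np.ndarray:
    """Axis-aligned 9-px-wide capsule in a padded canvas."""
    from omniflow import ShapeSpec, make_shape

    shape = make_shape(ShapeSpec(kind="rod", width=9, length=50, seed=0))
    canvas = np.zeros(tuple(s + 8 for s in shape.array.shape), dtype=int)
    canvas[4:-4, 4:-4][shape.array > 0] = 1
    return canvas


@pytest.fixture
def small_scene():
    from omniflow import SceneSpec, make_scene

    return make_scene(
        SceneSpec(
            shape=(192, 192), n_cells=6, packing="colony",
            kinds=("rod", "filament"), seed=11,
        )
    )
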