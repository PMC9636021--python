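"""Seeded generator of synthetic bacterial morphologies.

Label images emulating the shapes a bacterial segmentation pipeline must
handle — rods (capsules: rectangles with half-disk caps), curved
filaments (constant-width dilations of a smoothed random-walk
centerline), branched forms (dilated random trees, Streptomyces-like),
disks, and in 3D spheres and spherocylinders — at realistic pixel scales
(widths ~5–15 px, lengths up to hundreds of px).  Scenes place shapes by
rejection sampling, either sparse (pairwise separated) or as packed
colonies in which cells are slid into contact.  Everything is
deterministic under a seed, so the full pipeline (labels → fields →
perturb → reconstruct → metrics) closes into a self-contained test loop
with no external data.

Widths below 3 px are rejected: the flow field is not well-defined at
boundary pixels of thinner cells, so 3 px (a 9-px-square footprint in
2D) is the minimal supported cell size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core_labels import LabelImage, label_adjacency

__all__ = [
    "ShapeSpec",
    "SceneSpec",
    "make_shape",
    "make_scene",
    "perturb_fields",
    "render_intensity",
]

KINDS = ("rod", "filament", "branched", "disk", "sphere3d", "spherocylinder3d")


@dataclass
class ShapeSpec:
    """One synthetic cell shape.

    width is the full cell width in px (≥ 3); length the centerline
    length; curvature the per-step heading change std (radians) for
    filaments; n_branches the branch count for trees.
    """

    kind: str = "rod"
    width: float = 9.0
    length: float = 40.0
    curvature: float = 0.05
    n_branches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.width < 3:
            raise ValueError("cells must be at least 3 px wide")


@dataclass
class SceneSpec:
    """A multi-cell scene."""

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 10
    packing: str = "sparse"  # or "colony"
    kinds: Sequence[str] = ("rod",)
    width_range: tuple[float, float] = (5.0, 15.0)
    length_range: tuple[float, float] = (20.0, 80.0)
    seed: int = 0
    max_attempts: int = 200  # placement attempts per cell

    def __post_init__(self) -> None:
        if self.packing not in ("sparse", "colony"):
            raise ValueError("packing must be 'sparse' or 'colony'")
        if self.width_range[0] < 3:
            raise ValueError("cells must be at least 3 px wide")


def _dist_to_segments(shape, points: np.ndarray) -> np.ndarray:
    """Distance from every grid point to a polyline given by `points`.

    Computed as an exact EDT of the rasterized (densely sampled)
    centerline, accurate to sub-pixel for dilation purposes.
    """
    canvas = np.ones(shape, dtype=bool)
    ij = np.round(points).astype(int)
    ij = ij[np.all((ij >= 0) & (ij < np.asarray(shape)), axis=1)]
    canvas[tuple(ij.T)] = False
    return ndimage.distance_transform_edt(canvas)


def _walk(rng, start, heading, length, curvature, step=0.5):
    pts = [np.asarray(start, dtype=float)]
    h = float(heading)
    n = max(1, int(round(length / step)))
    for _ in range(n):
        h += rng.normal(0.0, curvature * step)
        pts.append(pts[-1] + step * np.array([math.sin(h), math.cos(h)]))
    return np.asarray(pts)


def _capsule_mask(shape, p0, p1, width) -> np.ndarray:
    """Pixels within width/2 of the segment p0–p1 (2D or 3D)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    x = np.stack(grids, axis=-1).astype(float)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        dist = np.linalg.norm(x - p0, axis=-1)
    else:
        t = np.clip(((x - p0) @ d) / denom, 0.0, 1.0)
        proj = p0[None] + t[..., None] * d[None]
        dist = np.linalg.norm(x - proj.reshape(x.shape), axis=-1)
    return dist <= width / 2.0


def make_shape(spec: ShapeSpec) -> LabelImage:
    """Rasterize one shape (label 1) on a canvas sized to fit it.

    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.width
    margin = int(math.ceil(w)) + 2

    if spec.kind == "disk":
        r = spec.length / 2.0
        n = int(math.ceil(2 * r)) + 2 * margin
        yy, xx = np.mgrid[:n, :n]
        c = (n - 1) / 2.0
        mask = (yy - c) ** 2 + (xx - c) ** 2 <= r ** 2
    elif spec.kind == "rod":
        body = max(spec.length - w, 0.0)
        n0 = int(math.ceil(w)) + 2 * margin
        n1 = int(math.ceil(body + w)) + 2 * margin
        c0 = (n0 - 1) / 2.0
        p0 = (c0, margin + w / 2.0)
        p1 = (c0, margin + w / 2.0 + body)
        mask = _capsule_mask((n0, n1), p0, p1, w)
    elif spec.kind in ("filament", "branched"):
        n = int(math.ceil(spec.length)) + 2 * margin
        center = np.array([n / 2.0, n / 2.0])
        pts_list = [
            _walk(rng, center, rng.uniform(0, 2 * math.pi), spec.length, spec.curvature)
        ]
        if spec.kind == "branched":
            trunk = pts_list[0]
            for _ in range(spec.n_branches):
                i = rng.integers(len(trunk) // 4, 3 * len(trunk) // 4)
                pts_list.append(
                    _walk(
                        rng, trunk[i], rng.uniform(0, 2 * math.pi),
                        spec.length / 2.0, spec.curvature,
                    )
                )
        all_pts = np.concatenate(pts_list, axis=0)
        mask = _dist_to_segments((n, n), all_pts) <= w / 2.0
    elif spec.kind == "sphere3d":
        r = spec.length / 2.0
        n = int(math.ceil(2 * r)) + 6
        zz, yy, xx = np.mgrid[:n, :n, :n]
        c = (n - 1) / 2.0
        mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r ** 2
    elif spec.kind == "spherocylinder3d":
        body = max(spec.length - w, 0.0)
        n0 = int(math.ceil(w)) + 4
        n1 = int(math.ceil(body + w)) + 4
        c0 = (n0 - 1) / 2.0
        p0 = (c0, c0, 2 + w / 2.0)
        p1 = (c0, c0, 2 + w / 2.0 + body)
        mask = _capsule_mask((n0, n0, n1), p0, p1, w)
    else:  # pragma: no cover
        raise ValueError(spec.kind)

    # crop to content with a 1-px margin
    if mask.any():
        sl = ndimage.find_objects(mask.astype(np.int8))[0]
        grown = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, n))
            for s, n in zip(sl, mask.shape)
        )
        mask = mask[grown]
    return LabelImage(mask.astype(np.int32))


def _rotate_mask(mask: np.ndarray, angle_deg: float) -> np.ndarray:
    rot = ndimage.rotate(
        mask.astype(np.uint8), angle_deg, order=0, reshape=True, prefilter=False
    )
    if rot.any():
        sl = ndimage.find_objects(rot)[0]
        rot = rot[sl]
    return rot.astype(bool)


def _try_place(canvas: np.ndarray, mask: np.ndarray, pos: tuple[int, ...],
               gap: int) -> bool:
    """True if `mask` fits at top-left `pos` without overlapping existing
    labels (with `gap` px of clearance when gap > 0)."""
    sl = tuple(slice(p, p + s) for p, s in zip(pos, mask.shape))
    if any(s.stop > n or s.start < 0 for s, n in zip(sl, canvas.shape)):
        return False
    region = canvas[sl] > 0
    if gap > 0:
        # full-connectivity dilation so diagonal contact also counts
        struct = ndimage.generate_binary_structure(canvas.ndim, canvas.ndim)
        region = ndimage.binary_dilation(
            canvas > 0, structure=struct, iterations=gap
        )[sl]
    return not (region & mask).any()


def make_scene(spec: SceneSpec) -> LabelImage:
    """Place n_cells shapes into one scene by rejection sampling.

    Sparse packing keeps a 1-px clearance so cells are pairwise disjoint
    and non-touching; colony packing slides each new cell toward the
    colony centroid until the step before contact, producing densely
    touching (but never overlapping) groups.  Raises if fewer than
    n_cells could be placed within the attempt budget, reporting the
    achieved count.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros(spec.shape, dtype=np.int32)
    placed = 0
    dil_cache: np.ndarray | None = None

    for cell in range(1, spec.n_cells + 1):
        ok = False
        for _attempt in range(spec.max_attempts):
            kind = rng.choice(list(spec.kinds))
            sub = ShapeSpec(
                kind=kind,
                width=float(rng.uniform(*spec.width_range)),
                length=float(rng.uniform(*spec.length_range)),
                curvature=0.05,
                n_branches=int(rng.integers(1, 3)),
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            mask = make_shape(sub).array.astype(bool)
            if mask.ndim == 2:
                mask = _rotate_mask(mask, float(rng.uniform(0, 360)))
            if any(m >= n for m, n in zip(mask.shape, spec.shape)):
                continue
            pos = tuple(
                int(rng.integers(0, n - m + 1))
                for m, n in zip(mask.shape, spec.shape)
            )
            if spec.packing == "sparse" or placed == 0:
                gap = 1 if spec.packing == "sparse" else 0
                if _try_place(canvas, mask, pos, gap=gap):
                    sl = tuple(slice(p, p + s) for p, s in zip(pos, mask.shape))
                    canvas[sl][mask] = cell
                    ok = True
                    break
            else:
                # colony: slide toward the colony centroid until the step
                # before overlap -> contact without overlap
                if not _try_place(canvas, mask, pos, gap=0):
                    continue
                centroid = np.mean(np.argwhere(canvas > 0), axis=0)
                here = np.asarray(pos, dtype=float)
                target = centroid - np.asarray(mask.shape) / 2.0
                direction = target - here
                norm = np.linalg.norm(direction)
                if norm > 0:
                    step = direction / norm
                    while True:
                        nxt = tuple(int(round(v)) for v in (here + step))
                        if nxt == tuple(int(round(v)) for v in here):
                            here += step
                            continue
                        if not _try_place(canvas, mask, nxt, gap=0):
                            break
                        here = np.asarray(nxt, dtype=float)
                        if np.linalg.norm(target - here) < 1.0:
                            break
                pos = tuple(int(round(v)) for v in here)
                sl = tuple(slice(p, p + s) for p, s in zip(pos, mask.shape))
                canvas[sl][mask] = cell
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could only place {placed} of {spec.n_cells} cells "
                f"within {spec.max_attempts} attempts each"
            )
        placed += 1
    return LabelImage(canvas)


def perturb_fields(phi, flow, noise_sigma: float, rng: np.random.Generator):
    """Emulate prediction error: Gaussian noise on the flow components
    followed by renormalization to unit magnitude on the foreground, and
    Gaussian noise (same σ, in px) on the distance field clipped at 0.

    Returns (phi_array, flow_components) as plain arrays.
    """
    from .eikonal import DistanceField
    from .fields import FlowField

    phi_arr = phi.phi if isinstance(phi, DistanceField) else np.asarray(phi, dtype=np.float64)
    comps = (flow.components if isinstance(flow, FlowField) else np.asarray(flow)).copy()
    fg = phi_arr > 0
    if noise_sigma > 0:
        comps = comps + rng.normal(0.0, noise_sigma, comps.shape)
        mag = np.sqrt((comps ** 2).sum(axis=0))
        ok = fg & (mag > 1e-8)
        out = np.zeros_like(comps)
        np.divide(comps, mag[None], out=out, where=ok[None])
        comps = out
        phi_arr = np.where(
            fg, np.clip(phi_arr + rng.normal(0.0, noise_sigma, phi_arr.shape), 0, None), 0.0
        )
    else:
        comps = np.where(fg[None], comps, 0.0)
    return phi_arr, comps


def render_intensity(labels, rng: np.random.Generator | None = None) -> np.ndarray:
    """Phase-contrast-like rendering for demos: dark cell interiors on a
    brighter background with a 1-px bright halo, blurred plus shot noise.
    Deterministic under the rng seed; values in [0, 1]."""
    rng = rng or np.random.default_rng()
    arr = labels.array if isinstance(labels, LabelImage) else np.asarray(labels)
    fg = arr > 0
    halo = ndimage.binary_dilation(fg) & ~fg
    img = np.full(arr.shape, 0.6)
    img[fg] = 0.25
    img[halo] = 0.9
    img = ndimage.gaussian_filter(img, 1.0)
    img = img + rng.normal(0.0, 0.02, img.shape)
    return np.clip(img, 0.0, 1.0)
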