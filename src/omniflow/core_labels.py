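"""Instance label images and n-color annotation encoding.

A label image is a D-dimensional integer grid in which 0 is background and
each positive id is one cell instance.  The n-color representation recodes
an instance map with a handful of repeating colors such that no two
touching instances share a color — by the four-color theorem four colors
suffice for planar non-overlapping masks, and four to six are enough in
practice for pixel maps.  Annotators use it to edit dense colonies with a
tiny palette; :func:`ncolor_decode` recovers instances as connected
components within each color.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "LabelImage",
    "NColorImage",
    "read_labels",
    "write_labels",
    "ncolor_encode",
    "ncolor_decode",
]


@dataclass
class LabelImage:
    """Integer instance map; 0 = background, arrays are (y, x) or (z, y, x)."""

    array: np.ndarray
    pixel_size: Optional[float] = None  # µm per pixel, if known

    def __post_init__(self) -> None:
        arr = np.asarray(self.array)
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
                arr = arr.astype(np.int64)
            else:
                raise ValueError("label image must hold integer values")
        if arr.ndim not in (2, 3):
            raise ValueError("label image must be 2D or 3D")
        if arr.min() < 0:
            raise ValueError("label ids must be nonnegative (0 = background)")
        self.array = arr

    @property
    def dim(self) -> int:
        return self.array.ndim

    @property
    def ids(self) -> np.ndarray:
        """Sorted nonzero label ids present in the image."""
        u = np.unique(self.array)
        return u[u > 0]

    @property
    def n_labels(self) -> int:
        return int(self.ids.size)


@dataclass
class NColorImage:
    """Small-integer recoloring of an instance map (values 0..C, C ≤ 6 normally)."""

    array: np.ndarray
    palette_size: int


def as_label_array(labels) -> np.ndarray:
    """Accept a LabelImage or a bare integer array; return the array."""
    if isinstance(labels, LabelImage):
        return labels.array
    return LabelImage(np.asarray(labels)).array


def read_labels(path) -> LabelImage:
    """Read a label image from PNG (8/16-bit grayscale) or TIFF.

    A multi-page TIFF is read as a 3D (z, y, x) volume.  RGB payloads are
    rejected: a label image is a single integer channel.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and suffix not in (".tif", ".tiff"):
        raise ValueError(f"{path}: not an integer label image (RGB/RGBA payload)")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
            arr = arr.astype(np.int64)
        else:
            raise ValueError(f"{path}: not an integer label image")
    return LabelImage(arr)


def write_labels(labels, path) -> None:
    """Write a label image; round-trips bit-exactly through read_labels.

    PNG gets 8- or 16-bit depending on the maximum id; TIFF escalates to
    32-bit when ids exceed 16 bits.  3D volumes must go to (multi-page)
    TIFF.
    """
    arr = as_label_array(labels)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vmax = int(arr.max()) if arr.size else 0
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        dtype = np.uint16 if vmax < 2 ** 16 else np.uint32
        tifffile.imwrite(path, arr.astype(dtype), photometric="minisblack")
    elif suffix == ".png":
        import imageio.v3 as iio

        if arr.ndim != 2:
            raise ValueError("PNG output supports 2D label images only; use TIFF for 3D")
        if vmax >= 2 ** 16:
            raise ValueError("label ids exceed 16 bits; write a TIFF instead")
        dtype = np.uint8 if vmax < 2 ** 8 else np.uint16
        iio.imwrite(path, arr.astype(dtype))
    else:
        raise ValueError(f"unsupported label format {suffix!r} (use .png/.tif)")


def _structure(ndim: int) -> np.ndarray:
    # full connectivity (8-connected in 2D): diagonal contact counts
    return ndimage.generate_binary_structure(ndim, ndim)


def label_adjacency(labels) -> dict[int, set[int]]:
    """Adjacency graph of instances: two labels are adjacent when any of
    their pixels are within a 1-pixel (full-connectivity) dilation of each
    other, i.e. touch up to diagonals."""
    arr = as_label_array(labels)
    adj: dict[int, set[int]] = {int(i): set() for i in np.unique(arr) if i > 0}
    nd = arr.ndim
    shifts = []
    for off in np.ndindex(*(3,) * nd):
        off = tuple(o - 1 for o in off)
        if any(off) and off > tuple([0] * nd):  # half the offsets; symmetry covers the rest
            shifts.append(off)
    for off in shifts:
        src = tuple(slice(max(o, 0), n + min(o, 0)) for o, n in zip(off, arr.shape))
        dst = tuple(slice(max(-o, 0), n + min(-o, 0)) for o, n in zip(off, arr.shape))
        a, b = arr[src], arr[dst]
        touch = (a > 0) & (b > 0) & (a != b)
        if touch.any():
            pairs = np.unique(np.stack([a[touch], b[touch]], axis=1), axis=0)
            for x, y in pairs:
                adj[int(x)].add(int(y))
                adj[int(y)].add(int(x))
    return adj


def ncolor_encode(labels) -> NColorImage:
    """Greedy graph coloring of the instance-adjacency graph.

    Labels are colored in order of descending area (ties by id), each
    taking the smallest color unused by its already-colored neighbours.
    Planar non-overlapping masks need at most four colors in the
    continuum; six covers every practical pixelated annotation.  A
    coloring that exceeds six signals pathological adjacency and is
    reported with a warning, not an error.
    """
    arr = as_label_array(labels)
    if arr.ndim != 2:
        raise ValueError("n-color encoding is defined for 2D label images")
    adj = label_adjacency(arr)
    ids = sorted(adj)
    areas = ndimage.sum_labels(np.ones_like(arr), arr, ids) if ids else []
    order = sorted(ids, key=lambda i: (-areas[ids.index(i)], i))
    color: dict[int, int] = {}
    for lab in order:
        used = {color[n] for n in adj[lab] if n in color}
        c = 1
        while c in used:
            c += 1
        color[lab] = c
    c_max = max(color.values(), default=0)
    if c_max > 6:
        warnings.warn(
            f"n-color encoding needed {c_max} colors; adjacency is pathological",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.zeros(arr.shape, dtype=np.uint8)
    for lab, c in color.items():
        out[arr == lab] = c
    return NColorImage(out, palette_size=c_max)


def ncolor_decode(ncolor) -> LabelImage:
    """Recover instances from an n-color image: connected components
    (full connectivity) within each color become distinct labels."""
    arr = ncolor.array if isinstance(ncolor, NColorImage) else np.asarray(ncolor)
    out = np.zeros(arr.shape, dtype=np.int32)
    nxt = 0
    for c in np.unique(arr):
        if c == 0:
            continue
        comp, n = ndimage.label(arr == c, structure=_structure(arr.ndim))
        out[comp > 0] = comp[comp > 0] + nxt
        nxt += n
    return LabelImage(out)
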