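"""Eikonal distance-field solvers for instance label images.

The central object is the smooth distance field φ: the solution of the
eikonal equation |∇φ| = 1/f inside each labeled region, with φ = 0 on the
background.  With unit speed (f ≡ 1) this is the geodesic distance to the
region boundary, but solved with an iterative Godunov upwind scheme that
also samples diagonal (ordinal) neighbours and combines the two partial
updates by a geometric mean.  Compared with an exact Euclidean distance
transform — or with the cardinal-only upwind scheme — the resulting field
is smooth across pixelated boundaries, which matters because its
normalized gradient is used downstream as a flow field.

Three solvers share one interface:

* :func:`smooth_fim_distance` — the cardinal+ordinal geometric-mean scheme.
* :func:`cartesian_godunov_distance` — cardinal-only baseline; reproduces
  the ridge artifacts of marching-type solvers along diagonals.
* :func:`exact_edt` — exact Euclidean distance transform (oracle/baseline).

All solvers run per label: when computing the field of one instance every
other instance is treated as background, so touching cells each carry a
boundary-relative field.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .core_labels import LabelImage, as_label_array

__all__ = [
    "SolverConfig",
    "DistanceField",
    "smooth_fim_distance",
    "cartesian_godunov_distance",
    "exact_edt",
]

_SQRT2 = math.sqrt(2.0)


@dataclass
class SolverConfig:
    """Convergence settings for the iterative eikonal solvers.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the maximum per-pixel update, in pixels.
    max_iter : int or None
        Iteration cap.  ``None`` selects ``10 * ceil(max exact EDT)`` per
        label (iteration count scales linearly with the maximum of the
        exact distance), with a floor of 20 sweeps.
    mode : str
        One of ``{"smooth_fim", "cartesian_godunov", "exact_edt"}``; used
        by :func:`distance_field` dispatch and recorded in provenance.
    """

    tol: float = 1e-6
    max_iter: Optional[int] = None
    mode: str = "smooth_fim"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter is not None and self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class DistanceField:
    """A per-pixel distance field φ (pixels; 0 on background)."""

    phi: np.ndarray
    converged: bool = True
    iterations: int = 0

    @property
    def dim(self) -> int:
        return self.phi.ndim


def _smooth_update_2d(phi: np.ndarray) -> np.ndarray:
    """One Jacobi evaluation of the cardinal+ordinal update on a padded grid.

    `phi` carries a 1-pixel zero pad; the returned array is the update for
    the interior.  δ = f = 1 so every step adds unit distance.
    """
    minx = np.minimum(phi[:-2, 1:-1], phi[2:, 1:-1])
    miny = np.minimum(phi[1:-1, :-2], phi[1:-1, 2:])
    mina = np.minimum(phi[:-2, :-2], phi[2:, 2:])
    minb = np.minimum(phi[2:, :-2], phi[:-2, 2:])

    d = minx - miny
    uxy = np.where(
        np.abs(d) > _SQRT2,
        np.minimum(minx, miny) + 1.0,
        0.5 * (minx + miny + np.sqrt(np.maximum(2.0 - d * d, 0.0))),
    )
    d = mina - minb
    uab = np.where(
        np.abs(d) > 2.0,
        np.minimum(mina, minb) + _SQRT2,
        0.5 * (mina + minb + np.sqrt(np.maximum(4.0 - d * d, 0.0))),
    )
    return np.sqrt(uxy * uab)


def _godunov_cardinal(mins: list[np.ndarray]) -> np.ndarray:
    """Godunov upwind solution of sum_i max(u - m_i, 0)^2 = 1 (unit step).

    `mins` holds, per axis, the smaller of the two axis neighbours.  Works
    for any dimensionality; the standard sorted-accumulation solve.
    """
    stack = np.sort(np.stack(mins, axis=0), axis=0)
    u = stack[0] + 1.0
    for k in range(1, stack.shape[0]):
        a = stack[:k + 1]
        need = u > stack[k]
        if not np.any(need):
            break
        s = a.sum(axis=0)
        q = (a * a).sum(axis=0)
        n = k + 1.0
        disc = s * s - n * (q - 1.0)
        u_k = (s + np.sqrt(np.maximum(disc, 0.0))) / n
        u = np.where(need, u_k, u)
    return u


def _cardinal_update_2d(phi: np.ndarray) -> np.ndarray:
    minx = np.minimum(phi[:-2, 1:-1], phi[2:, 1:-1])
    miny = np.minimum(phi[1:-1, :-2], phi[1:-1, 2:])
    return _godunov_cardinal([minx, miny])


def _cardinal_update_3d(phi: np.ndarray) -> np.ndarray:
    mins = []
    for ax in range(3):
        lo = tuple(slice(0, -2) if a == ax else slice(1, -1) for a in range(3))
        hi = tuple(slice(2, None) if a == ax else slice(1, -1) for a in range(3))
        mins.append(np.minimum(phi[lo], phi[hi]))
    return _godunov_cardinal(mins)


def _ordinal_update_plane(phi: np.ndarray, ax0: int, ax1: int) -> np.ndarray:
    """Ordinal (diagonal) partial update within the (ax0, ax1) plane of a
    padded 3D grid: same two-branch rule as in 2D, step sqrt(2)."""

    def sl(d0: int, d1: int) -> tuple:
        out = [slice(1, -1)] * 3
        out[ax0] = slice(1 + d0, phi.shape[ax0] - 1 + d0)
        out[ax1] = slice(1 + d1, phi.shape[ax1] - 1 + d1)
        return tuple(out)

    mina = np.minimum(phi[sl(-1, -1)], phi[sl(1, 1)])
    minb = np.minimum(phi[sl(1, -1)], phi[sl(-1, 1)])
    d = mina - minb
    return np.where(
        np.abs(d) > 2.0,
        np.minimum(mina, minb) + _SQRT2,
        0.5 * (mina + minb + np.sqrt(np.maximum(4.0 - d * d, 0.0))),
    )


def _smooth_update_3d(phi: np.ndarray) -> np.ndarray:
    # Geometric mean of the 3-axis cardinal update and the three
    # plane-wise ordinal updates — the dimension-lifted analogue of
    # sqrt(U^xy * U^ab).
    u = _cardinal_update_3d(phi)
    prod = u.copy()
    for ax0, ax1 in ((0, 1), (0, 2), (1, 2)):
        prod *= _ordinal_update_plane(phi, ax0, ax1)
    return prod ** 0.25


def _solve_mask(mask: np.ndarray, config: SolverConfig, smooth: bool) -> DistanceField:
    """Iterate the upwind update to its ascending fixed point on one mask.

    φ starts at 0 everywhere; background stays clamped at 0 so foreground
    values grow monotonically toward the fixed point (each sweep the update
    is monotone in the neighbour values, and enforced with a max for
    robustness near the branch switch).
    """
    if not mask.any():
        return DistanceField(np.zeros(mask.shape, dtype=np.float64), True, 0)

    max_iter = config.max_iter
    if max_iter is None:
        dmax = float(ndimage.distance_transform_edt(mask).max())
        max_iter = max(20, int(math.ceil(10.0 * dmax)))

    pad = np.zeros(tuple(s + 2 for s in mask.shape), dtype=np.float64)
    core = tuple(slice(1, -1) for _ in mask.shape)
    if mask.ndim == 2:
        update = _smooth_update_2d if smooth else _cardinal_update_2d
    elif mask.ndim == 3:
        update = _smooth_update_3d if smooth else _cardinal_update_3d
    else:
        raise ValueError("only 2D and 3D grids are supported")

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = update(pad)
        new = np.where(mask, np.maximum(new, pad[core]), 0.0)
        change = float(np.max(np.abs(new - pad[core])))
        pad[core] = new
        if change < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"eikonal solver did not converge within {max_iter} sweeps "
            f"(last max update {change:.3g} px)",
            RuntimeWarning,
            stacklevel=3,
        )
    return DistanceField(pad[core], converged, it)


def _per_label(labels, fn) -> np.ndarray:
    """Apply a mask->field solver per label over padded bounding boxes."""
    arr = as_label_array(labels)
    out = np.zeros(arr.shape, dtype=np.float64)
    slices = ndimage.find_objects(arr)
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        grown = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, n))
            for s, n in zip(sl, arr.shape)
        )
        mask = arr[grown] == idx
        out[grown][mask] = fn(mask)[mask]
    return out


def smooth_fim_distance(labels, config: SolverConfig | None = None) -> DistanceField:
    """Smooth distance field via the cardinal+ordinal geometric-mean scheme.

    Solves, per label, the Godunov upwind discretization of |∇φ| = 1 with
    the two-branch cardinal update U^xy (switch at √2·δ), the diagonal
    ordinal update U^ab (switch at 2δ), and the combined value
    φ = sqrt(U^xy · U^ab), iterated to convergence.  Unit speed and δ = f
    so each update adds unit pixel steps.

    Parameters
    ----------
    labels : LabelImage or integer ndarray
        Instance map, 0 = background.
    config : SolverConfig, optional

    Returns
    -------
    DistanceField
        φ = 0 on background, > 0 on foreground; interior pixels (φ ≥ 1)
        are those not classified as boundary (0 < φ < 1).
    """
    config = config or SolverConfig()
    flags: list[bool] = []
    iters: list[int] = []

    def fn(mask: np.ndarray) -> np.ndarray:
        fld = _solve_mask(mask, config, smooth=True)
        flags.append(fld.converged)
        iters.append(fld.iterations)
        return fld.phi

    phi = _per_label(labels, fn)
    return DistanceField(phi, all(flags) if flags else True, max(iters, default=0))


def cartesian_godunov_distance(labels, config: SolverConfig | None = None) -> DistanceField:
    """Cardinal-only Godunov upwind distance (no ordinal sampling, no
    geometric mean).  Converges to the same boundary-distance notion but
    carries ridge artifacts along diagonals from the pixelated boundary —
    kept as the comparison baseline for the smooth solver."""
    config = config or SolverConfig()
    flags: list[bool] = []
    iters: list[int] = []

    def fn(mask: np.ndarray) -> np.ndarray:
        fld = _solve_mask(mask, config, smooth=False)
        flags.append(fld.converged)
        iters.append(fld.iterations)
        return fld.phi

    phi = _per_label(labels, fn)
    return DistanceField(phi, all(flags) if flags else True, max(iters, default=0))


def exact_edt(labels) -> DistanceField:
    """Exact Euclidean distance from each foreground pixel to the nearest
    background pixel, computed per label (other labels are background)."""

    def fn(mask: np.ndarray) -> np.ndarray:
        return ndimage.distance_transform_edt(mask)

    return DistanceField(_per_label(labels, fn), True, 0)


def distance_field(labels, config: SolverConfig | None = None) -> DistanceField:
    """Dispatch on ``config.mode``."""
    config = config or SolverConfig()
    if config.mode == "smooth_fim":
        return smooth_fim_distance(labels, config)
    if config.mode == "cartesian_godunov":
        return cartesian_godunov_distance(labels, config)
    if config.mode == "exact_edt":
        return exact_edt(labels)
    raise ValueError(f"unknown solver mode {config.mode!r}")
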