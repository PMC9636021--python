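"""Prediction-class generation: distance, flow and boundary fields.

From a label image three fields are derived:

* the smooth eikonal distance field φ (see :mod:`omniflow.eikonal`);
* the flow field — the normalized gradient of φ, a unit vector field on
  the foreground pointing from the cell boundary toward the skeleton
  (the stationary points of φ);
* the boundary map — exactly the pixels with 0 < φ < 1.

These are the regression targets a segmentation network is trained
against; :func:`encode_targets` applies the value-range conventions
(flow × 5, background distance −5, boundary as logits in [−5, 5]) and
:func:`decode_targets` inverts them.  :func:`divergence_rescale` converts
the unit flow into the integration field used for mask reconstruction:
its magnitude is the min–max rescaled divergence, largest at boundaries
(where pixels must move) and smallest at skeletons (where they must stop).

The module also carries the two intensity-augmentation primitives used in
training (gamma and percentile normalization) and a joint random
crop/affine for images, labels and fields.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core_labels import as_label_array
from .eikonal import DistanceField, SolverConfig, smooth_fim_distance

__all__ = [
    "FlowField",
    "BoundaryMap",
    "EncodedTargets",
    "AugmentationConfig",
    "labels_to_fields",
    "encode_targets",
    "decode_targets",
    "divergence_rescale",
    "gamma_augment",
    "normalize_percentile",
    "random_crop_affine",
]

_EPS = 1e-8  # gradient-normalization cutoff; zero vector below it
_LOGIT_CLIP = 5.0


@dataclass
class FlowField:
    """D-component vector field, stored as an array of shape (D, *grid).

    Component order matches axis order of the grid: (flow_y, flow_x) in 2D,
    (flow_z, flow_y, flow_x) in 3D.  Unit magnitude on foreground before
    divergence rescaling, zero on background.
    """

    components: np.ndarray

    @property
    def dim(self) -> int:
        return self.components.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.components ** 2).sum(axis=0))


@dataclass
class BoundaryMap:
    """Binary boundary indicator (or probability in [0,1] from predictions)."""

    indicator: np.ndarray


@dataclass
class EncodedTargets:
    """Network-target encoding of (distance, flow, boundary)."""

    flow_scaled: np.ndarray      # flow × 5
    distance_enc: np.ndarray     # φ, with φ = 0 (background) set to −5
    boundary_logits: np.ndarray  # inverse sigmoid of [0,1] clamped to [−5,5]


@dataclass
class AugmentationConfig:
    """Training-augmentation settings.

    gamma_range and norm_percentiles are the published defaults; the affine
    ranges are this package's own (rotation anywhere on the circle, mild
    zoom, optional flip).
    """

    gamma_range: tuple[float, float] = (0.5, 1.25)
    norm_percentiles: tuple[float, float] = (0.01, 99.99)
    rotation_range: tuple[float, float] = (0.0, 360.0)  # degrees
    scale_range: tuple[float, float] = (0.75, 1.25)
    allow_flip: bool = True
    max_crop_attempts: int = 50

    def __post_init__(self) -> None:
        lo, hi = self.gamma_range
        if not (0 < lo <= hi):
            raise ValueError("gamma_range must be positive and ordered")
        plo, phi_ = self.norm_percentiles
        if not (0 <= plo < phi_ <= 100):
            raise ValueError("norm_percentiles must be ordered within [0, 100]")


def _phi_array(phi) -> np.ndarray:
    return phi.phi if isinstance(phi, DistanceField) else np.asarray(phi, dtype=np.float64)


def flow_from_phi(phi) -> FlowField:
    """Normalized gradient of φ by central differences (background = 0)."""
    arr = _phi_array(phi)
    grads = np.stack(np.gradient(arr), axis=0) if arr.ndim > 1 else arr
    mag = np.sqrt((grads ** 2).sum(axis=0))
    fg = arr > 0
    ok = fg & (mag > _EPS)
    flow = np.zeros_like(grads)
    np.divide(grads, mag[None], out=flow, where=ok[None])
    return FlowField(flow)


def labels_to_fields(
    labels, config: SolverConfig | None = None
) -> tuple[DistanceField, FlowField, BoundaryMap]:
    """Generate the three prediction classes from an instance map.

    Returns (φ, flow, boundary) with flow = ∇φ/|∇φ| on the foreground and
    boundary = (0 < φ < 1).
    """
    phi = smooth_fim_distance(labels, config)
    flow = flow_from_phi(phi)
    boundary = BoundaryMap((phi.phi > 0) & (phi.phi < 1))
    return phi, flow, boundary


def _boundary_to_logits(p: np.ndarray) -> np.ndarray:
    lo = 1.0 / (1.0 + math.exp(_LOGIT_CLIP))   # sigmoid(−5)
    hi = 1.0 / (1.0 + math.exp(-_LOGIT_CLIP))  # sigmoid(+5)
    q = np.clip(p.astype(np.float64), lo, hi)
    return np.log(q / (1.0 - q))


def _logits_to_boundary(z: np.ndarray) -> np.ndarray:
    p = 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))
    lo = 1.0 / (1.0 + math.exp(_LOGIT_CLIP))
    hi = 1.0 / (1.0 + math.exp(-_LOGIT_CLIP))
    # snap the clamp endpoints back to exact 0/1
    return np.clip((p - lo) / (hi - lo), 0.0, 1.0)


def encode_targets(phi, flow, boundary) -> EncodedTargets:
    """Map fields onto consistent value ranges for network regression:
    flow × 5; background distance −5; boundary [0,1] → logits [−5,5]."""
    arr = _phi_array(phi)
    comps = flow.components if isinstance(flow, FlowField) else np.asarray(flow)
    ind = boundary.indicator if isinstance(boundary, BoundaryMap) else np.asarray(boundary)
    if comps.shape[1:] != arr.shape or ind.shape != arr.shape:
        raise ValueError("field shapes are inconsistent")
    dist = np.where(arr == 0, -5.0, arr)
    return EncodedTargets(
        flow_scaled=comps * 5.0,
        distance_enc=dist,
        boundary_logits=_boundary_to_logits(ind),
    )


def decode_targets(enc: EncodedTargets) -> tuple[DistanceField, FlowField, BoundaryMap]:
    """Exact inverse of :func:`encode_targets` (lossless on foreground)."""
    phi = np.where(enc.distance_enc <= 0, 0.0, enc.distance_enc)
    return (
        DistanceField(phi),
        FlowField(np.asarray(enc.flow_scaled, dtype=np.float64) / 5.0),
        BoundaryMap(_logits_to_boundary(enc.boundary_logits)),
    )


def divergence(flow: FlowField) -> np.ndarray:
    """∇·flow by central differences."""
    comps = flow.components
    return sum(np.gradient(comps[i], axis=i) for i in range(comps.shape[0]))


def divergence_rescale(flow: FlowField, foreground: np.ndarray | None = None) -> FlowField:
    """Rescale flow magnitude by the min–max normalized divergence.

    The divergence of the unit flow is most positive at cell boundaries
    and most negative at skeletons; rescaled to [0, 1] over the foreground
    and multiplied onto the normalized flow, it makes boundary pixels move
    strongly under Euler integration while skeleton pixels stop.
    Background divergence is meaningless and excluded from the rescaling.
    """
    comps = flow.components
    if foreground is None:
        foreground = flow.magnitude() > _EPS
    div = divergence(flow)
    vals = div[foreground]
    if vals.size == 0:
        return FlowField(comps.copy())
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < _EPS:
        warnings.warn(
            "divergence is constant over the foreground; flow left unrescaled",
            RuntimeWarning,
            stacklevel=2,
        )
        return FlowField(comps.copy())
    scale = np.zeros(div.shape, dtype=np.float64)
    scale[foreground] = (div[foreground] - lo) / (hi - lo)
    return FlowField(comps * scale[None])


def gamma_augment(
    image: np.ndarray,
    config: AugmentationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Raise a [0,1]-normalized image to a random power γ ~ U(0.5, 1.25),
    simulating exposure/contrast variation."""
    config = config or AugmentationConfig()
    rng = rng or np.random.default_rng()
    img = np.asarray(image, dtype=np.float64)
    if img.size and (img.min() < 0 or img.max() > 1):
        raise ValueError("gamma_augment expects an image normalized to [0, 1]")
    gamma = rng.uniform(*config.gamma_range)
    return img ** gamma


def normalize_percentile(
    image: np.ndarray, config: AugmentationConfig | None = None
) -> np.ndarray:
    """Affine rescale sending the low/high intensity percentiles
    (default 0.01 and 99.99) to 0 and 1, clipped to [0, 1].

    The wide percentile range keeps sparse bright outliers (bubbles,
    glass) from crushing the bulk dynamic range without clipping dim
    single-cell foregrounds the way a 1/99 range does.
    """
    config = config or AugmentationConfig()
    img = np.asarray(image, dtype=np.float64)
    lo, hi = np.percentile(img, config.norm_percentiles)
    if hi - lo < _EPS:
        warnings.warn(
            "constant image; normalization is degenerate, returning 0.5",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(img.shape, 0.5)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def _affine_matrix_2d(
    rng: np.random.Generator, config: AugmentationConfig
) -> tuple[np.ndarray, float]:
    theta = math.radians(rng.uniform(*config.rotation_range))
    scale = rng.uniform(*config.scale_range)
    c, s = math.cos(theta), math.sin(theta)
    mat = np.array([[c, -s], [s, c]]) / scale
    if config.allow_flip and rng.random() < 0.5:
        mat = mat @ np.diag([1.0, -1.0])
    return mat, scale


def random_crop_affine(
    image: np.ndarray | None,
    labels,
    fields: tuple | None,
    crop_size: tuple[int, int],
    config: AugmentationConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Apply one random rotation/scale/flip + crop jointly to image, labels
    and fields (2D).

    Labels are resampled with nearest neighbour; image and field
    components with linear interpolation.  The flow is *not* renormalized
    after interpolation: its reduced magnitude where the field diverges
    (boundaries and skeletons) damps exactly the regions where
    interpolation artifacts live, which is the desired training target.
    Crops are retried (up to max_crop_attempts) until one contains
    foreground.

    Returns (image, labels, fields) with fields as (phi, FlowField,
    boundary) arrays, or with None passed through for absent inputs.
    """
    config = config or AugmentationConfig()
    rng = rng or np.random.default_rng()
    lab = as_label_array(labels)
    if lab.ndim != 2:
        raise ValueError("random_crop_affine supports 2D data")
    out_shape = tuple(int(s) for s in crop_size)

    for _ in range(config.max_crop_attempts):
        mat, _scale = _affine_matrix_2d(rng, config)
        # choose an output-center preimage uniformly over the input
        center_in = np.array([rng.uniform(0, s - 1) for s in lab.shape])
        center_out = (np.array(out_shape) - 1) / 2.0
        offset = center_in - mat @ center_out

        lab_t = ndimage.affine_transform(
            lab, mat, offset=offset, output_shape=out_shape, order=0,
            mode="constant", cval=0, prefilter=False,
        )
        if lab_t.any():
            break
    else:
        raise RuntimeError(
            f"no foreground found in {config.max_crop_attempts} crop attempts"
        )

    def warp(arr, order):
        return ndimage.affine_transform(
            np.asarray(arr, dtype=np.float64), mat, offset=offset,
            output_shape=out_shape, order=order, mode="constant", cval=0.0,
            prefilter=False,
        )

    img_t = warp(image, 1) if image is not None else None

    fields_t = None
    if fields is not None:
        phi, flow, boundary = fields
        phi_t = warp(_phi_array(phi), 1)
        comps = flow.components if isinstance(flow, FlowField) else np.asarray(flow)
        # rotate the vectors with the grid: components transform with the
        # inverse of the pixel-coordinate map (mat maps output->input)
        inv = np.linalg.inv(mat)
        warped = np.stack([warp(c, 1) for c in comps], axis=0)
        mixed = np.einsum("ij,j...->i...", inv, warped)
        # undo the zoom the coordinate inverse introduces: direction changes,
        # interpolation-induced magnitude loss is kept
        norm_in = np.sqrt((warped ** 2).sum(axis=0))
        norm_out = np.sqrt((mixed ** 2).sum(axis=0))
        fix = np.ones_like(norm_out)
        np.divide(norm_in, norm_out, out=fix, where=norm_out > _EPS)
        flow_t = FlowField(mixed * fix[None])
        bnd = boundary.indicator if isinstance(boundary, BoundaryMap) else np.asarray(boundary)
        bnd_t = warp(bnd.astype(np.float64), 1)
        fields_t = (phi_t, flow_t, bnd_t)

    return img_t, lab_t, fields_t
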