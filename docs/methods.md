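# Methods

This note records the mathematical model, the numerical choices, and the
scope and limitations of the package. Every quantitative claim here is
recomputed by the test suite (`tests/`) or by `scripts/acceptance.py`;
nothing is asserted from outside sources.

## 1. Distance model

For a labeled region Ω, the boundary distance φ solves the eikonal
equation |∇φ| = 1/f with φ = 0 on the complement of Ω and speed f = 1.
Each label is solved independently on its padded bounding box, with
other labels treated as background, so touching cells get independent
fields that vanish at their shared interface.

### Smooth fast-iterative update (2D)

On a unit grid (δ = 1), each pixel combines two Godunov-style updates:

- **Cardinal** (axis neighbors): with mx = min of the two x-neighbors and
  my = min of the two y-neighbors, U_xy = min(mx, my) + 1 if
  |mx − my| ≥ √2·δ/f, otherwise the two-sided quadratic solution
  ½·(mx + my + √(2δ²/f² − (mx − my)²)).
- **Ordinal** (diagonal neighbors, spacing √2·δ): the same scheme with
  threshold 2δ/f.

The update is their geometric mean, φ = √(U_xy · U_ord). Iteration starts
from φ ≡ 0 and proceeds by Jacobi sweeps with `np.maximum(new, old)`
enforcement, which makes the sequence monotone non-decreasing and
convergent to the ascending fixed point (tolerance 1e-6; iteration cap
10× the exact-EDT maximum, floor 20, with a warning on non-convergence).
Starting from zero rather than a large value is what yields the
*smooth* ridge behavior: along a skeleton the two stencils disagree, and
their geometric mean rounds the crease left by the exact transform.

**Accuracy.** On disks of radius 20–48 px the smooth field deviates from
the exact EDT by at most 1.5 px (max-norm); the median eikonal residual
| |∇φ| − 1 | away from boundary and ridge is below 0.15 (both are
acceptance tests). A useful exact fixed point: a flat edge has depth-1
value φ = 1.0 exactly (cardinal and ordinal updates both give 1), so the
boundary band 0 < φ < 1 contains only high-curvature pixels on straight
edges.

### 3D generalization

There is no unique 3D analogue of the ordinal stencil; this package uses
the geometric mean of four updates — the 3-axis cardinal Godunov solve
and the three plane-wise ordinal (face-diagonal) solves — i.e.
φ = (U_xyz · U_ab,xy · U_ab,yz · U_ab,xz)^(1/4). This preserves the
properties that matter downstream (smooth ridges, correct flat-face
depth-1 value) and round-trips a 24³ spherocylinder at IoU ≥ 0.85.

### Why not the exact EDT

The exact transform is kept (`exact_edt`, per-label
`scipy.ndimage.distance_transform_edt`) as the oracle and for the
diameter constant, but its gradient is piecewise constant in direction:
on a straight edge rotated ~15° off-axis, the flow-angle variance sampled
5 px inside the boundary is strictly larger for the cardinal Godunov
solver than for the smooth solver (acceptance test). The fixture is a
*rotated* rectangle deliberately: for an axis-aligned rectangle both
solvers produce exactly uniform flow (zero variance), so the contrast
only appears when the rasterized boundary is pixelated. At larger angles
(≳30°) staircase aliasing dominates both solvers and the ordering is no
longer reliable; the test uses 15°.

## 2. Flow fields and training targets

The flow field is the normalized gradient of φ (central differences via
`np.gradient`; magnitudes below 1e-8 are zeroed). The boundary map is
0 < φ < 1. `encode_targets` packs (flow × 5, distance with background at
−5, boundary through a logit map of [0,1] onto [−5, 5] clamped at
sigmoid(±5)); `decode_targets` inverts it exactly on the foreground and
snaps the clamp points back to 0/1.

Before integration, flow magnitudes are replaced by the min–max rescaled
divergence of the flow over the foreground (`divergence_rescale`), which
boosts motion near boundaries and stalls it on the skeleton. A
constant-divergence field is passed through unchanged with a warning.

Augmentation utilities (`gamma_augment`, `normalize_percentile`,
`random_crop_affine`) follow the conventions a training pipeline needs:
percentile normalization at (0.01, 99.99), gamma in [0.5, 1.25] on
normalized images only, and affine crops that rotate vector channels with
the image (nearest-neighbor for labels, linear for fields, magnitudes
restored after interpolation, retried until the crop contains
foreground).

## 3. Mask reconstruction

Every foreground pixel (φ > 0; the seed rule is independent of the
encoding convention) is integrated under

x_{t+1} = x_t + v(x_t) / (t + 1),

with v the divergence-rescaled flow interpolated multilinearly
(`map_coordinates`, order 1) and positions clamped to the domain. The
default step count is T = ⌈2 · max φ⌉: the harmonic partial sum
Σ 1/(t+1) ≈ ln T must cover the deepest skeleton distance, and doubling
the naive bound was sufficient in all round-trip suites. Final positions
are clustered with DBSCAN (eps = 2.0, min_samples = 5); noise points are
assigned to the nearest cluster via a k-d tree; an all-noise outcome
returns an empty labeling with a warning.

The 1/(t+1) suppression is load-bearing: with fixed unit steps the same
rotated capsules (width 9, length ~100, angles 10–40°) fragment into
several clusters at T = 100, while the suppressed scheme returns exactly
one (acceptance test). Axis-aligned capsules do *not* show the failure —
perfect symmetry cancels the axial flow component — which is why the
fixture is rotated.

## 4. Metrics

- **Matching**: one-to-one assignment maximizing total IoU
  (`linear_sum_assignment` on the negated IoU matrix, zero-IoU pairs
  dropped); verified against exhaustive permutation search.
- **JI(τ)** = TP / (TP + FP + FN) over τ ∈ {0.50, 0.55, …, 1.00};
  empty-vs-empty is defined as 1.
- **Errors per cell**: predictions are assigned to the ground-truth cell
  containing ≥ 0.75 of their area; a cell's error count is its surplus
  assigned predictions (split errors), or 1 if it receives none (miss).
- **Edge filtering**: masks touching the border are removed only if
  smaller than the 9 px minimal-cell area.
- **Diameters**: equivalent-area `2·√(A/π)` and effective `6·mean(φ)`.
  The constant 6 comes from the disk: mean(φ) = R/3, so d = 6·mean(φ);
  the radius-100 disk gives mean φ ≈ 33.5. On a discrete strip of width
  w the mean is (w+2)/4, not the continuum w/4 — the pixel-center
  distance convention adds ~0.5 px per side — so a width-5 filament has
  effective diameter ≈ 1.5·(w+2) ≈ 10.5 px regardless of length.

The diameter length-invariance contrast (spread < 5% for the effective
diameter, growth > 200% for the area diameter over 40–400 px) is
quantified at width 5 with `length` meaning centerline length plus width.
At width 8 the two clauses are close to jointly unattainable: the cap
fraction at the short end inflates the spread toward ~5% while the area
growth falls below 200%; width 5 separates them cleanly (measured spread
≈ 2.8%, growth ≈ 202%).

## 5. Synthetic generator

Shapes: capsules/rods (exact distance-to-segment rasterization),
filaments (EDT dilation of a random-walk centerline), branched trees,
disks, and 3D spheres/spherocylinders. Width is floored at 3 px — below
the minimal-cell scale no pixel reaches φ ≥ 1 and the shape is all
boundary. Scenes pack shapes either **sparse** (1 px clearance under
full connectivity, so no two labels touch even diagonally) or **colony**
(each shape slides toward the occupied centroid until the step before
overlap, producing realistic touching microcolonies). Placement failure
raises with the achieved count rather than silently returning fewer
cells.

`perturb_fields` adds seeded Gaussian noise to the fields (flow
renormalized, background distance pinned at its encoding value) to
emulate network prediction error; `render_intensity` produces
phase-contrast-like images (dark interior 0.25, bright halo 0.9,
background 0.6, Gaussian blur σ = 1, noise 0.02) for visual inspection
only — no claims are made about them.

The `SceneSpec` defaults (256² canvas, widths 5–15, lengths 20–80, mixed
rod/filament/branched, seeded) are the study conditions: the 50-scene
acceptance suite (seeds 100–149, alternating sparse/colony, 8 cells
each) round-trips at mean JI(0.5) = 1.0 with zero counting errors on
cells ≥ 9 px. Problem sizes were chosen to keep the full suite under a
few minutes while covering both packing regimes and all 2D shape kinds.

## 6. Limitations

- The generator produces idealized morphologies; it does not model
  septation, intensity textures beyond a cartoon, or densely layered 3D
  biofilms.
- The smooth solver's accuracy bound (≤ 1.5 px) is established on convex
  fixtures; concave necks can locally exceed it, though round trips on
  branched shapes still succeed.
- DBSCAN parameters (eps = 2.0, min_samples = 5) assume cells of at
  least the minimal-cell scale; reconstructing objects below ~9 px is
  out of scope by design.
- The 3D stencil is one reasonable generalization, validated on a single
  small fixture (24³), not a survey of alternatives.
- `n_color` encoding warns rather than fails if a label image needs more
  than 6 colors (possible for pathological adjacency graphs).
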