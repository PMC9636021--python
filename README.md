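# omniflow

Geometric core for boundary-aware instance segmentation of elongated and
irregular cells (bacteria in particular): smooth eikonal distance fields,
flow-field training targets, suppressed-Euler mask reconstruction,
instance-segmentation metrics, n-color label compression, and a seeded
synthetic morphology generator — everything around the neural network,
with no network required.

## Why a distance-field core?

Pixel-affinity and center-seeded methods degrade on long, thin, or curved
cells: a filament has no meaningful "center", and its skeleton carries
many spurious local maxima under the ordinary Euclidean distance
transform. This package builds on two ideas:

1. **A smooth eikonal distance field.** The boundary distance φ solves
   |∇φ| = 1 with φ = 0 outside the cell. Instead of the exact (piecewise
   conical, non-differentiable) solution, φ is computed with a fast
   iterative method whose update couples the cardinal and ordinal
   (diagonal) neighbor stencils through a geometric mean. The result
   stays within ~1 px of the exact transform but is smooth along ridges,
   so its normalized gradient — the **flow field** — points coherently
   from the skeleton to the boundary everywhere in the cell.

2. **Suppressed Euler integration.** Masks are recovered by moving every
   foreground pixel along the (reversed) flow and clustering the final
   positions (DBSCAN). The step size decays as 1/(t+1), so points settle
   onto the skeleton without overshooting and oscillating — plain fixed-step
   Euler fragments long cells into multiple clusters, the suppressed
   scheme does not (this contrast is an acceptance test).

Two analytic facts anchor the scale conventions, and are recomputed from
scratch by `scripts/acceptance.py`:

- For a disk of diameter d, the mean interior distance is d/6, so the
  **effective diameter** of any region is `6 · mean(φ)`. Unlike the
  equivalent-area diameter `2·√(A/π)`, it is invariant to cell length:
  a width-5 filament grown from 40 px to 400 px changes its effective
  diameter by under 5% while the area diameter triples.
- The **smallest viable cell** is a 3×3 square (9 px): it is the smallest
  all-foreground square containing a pixel with φ ≥ 1, i.e. a
  non-boundary pixel. Size filters default to this threshold.

## Worked example

```python
import numpy as np
from omniflow import (SceneSpec, make_scene, labels_to_fields,
                      reconstruct_masks, evaluate, effective_diameter,
                      smooth_fim_distance)

spec = SceneSpec(shape=(256, 256), n_cells=8, packing="colony",
                 kinds=("rod", "filament"), seed=3)
scene = make_scene(spec)                       # ground-truth label image
phi, flow, boundary = labels_to_fields(scene)  # training targets
masks = reconstruct_masks((phi, flow, boundary))
report = evaluate(scene, masks)

print("cells placed:     ", scene.n_labels)
print("cells recovered:  ", report.n_pred)
print("JI at tau=0.5:    ", round(report.ji[0], 4))
print("mean matched IoU: ", round(report.mean_matched_iou, 4))
print("errors per cell:  ", report.errors_per_cell.tolist())
d = effective_diameter(smooth_fim_distance(scene))
print("effective diameter:", round(d.effective_d, 2), "px")
```

Output (deterministic for the given seed):

```
cells placed:      8
cells recovered:   8
JI at tau=0.5:     1.0
mean matched IoU:  0.9989
errors per cell:   [0, 0, 0, 0, 0, 0, 0, 0]
effective diameter: 16.48 px
```

The same pipeline is available from the command line:

```
omniflow synth --n 8 --seed 3 --packing colony --out labels.tif
omniflow fields --labels labels.tif --out fields.tif
omniflow reconstruct --fields fields.tif --out masks.tif
omniflow eval --gt labels.tif --pred masks.tif --out report.json
omniflow roundtrip --labels labels.tif --out report.json   # all of the above
omniflow diameter --labels labels.tif --per-cell
```

Every command writes a `<out>.run.json` provenance sidecar recording the
resolved parameters.

## Package layout

| module | contents |
|---|---|
| `omniflow.eikonal` | smooth FIM solver (2D/3D), Godunov cardinal baseline, exact per-label EDT |
| `omniflow.fields` | flow fields, boundary maps, target encoding/decoding, divergence rescaling, augmentation |
| `omniflow.reconstruct` | suppressed Euler integration, DBSCAN clustering, mask reconstruction |
| `omniflow.metrics` | Hungarian IoU matching, JI(τ) curves, errors-per-cell, edge filtering, diameters |
| `omniflow.core_labels` | label-image I/O (TIFF/PNG), adjacency, n-color encode/decode |
| `omniflow.synthetic` | capsules, filaments, branched cells, disks, 3D shapes; sparse/colony scene packing; field perturbation; intensity rendering |
| `omniflow.cli` | `omniflow` command group |

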