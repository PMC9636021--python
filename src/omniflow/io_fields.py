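"""Field-stack I/O: multi-channel 32-bit float TIFF plus a JSON sidecar.

Channel order is (flow components in axis order, distance, boundary):
2D → (flow_y, flow_x, distance, boundary); 3D → (flow_z, flow_y, flow_x,
distance, boundary).  The sidecar (``<path>.json``) records channel
names, dimensionality and the value convention (raw or encoded) so a
stack is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .eikonal import DistanceField
from .fields import BoundaryMap, EncodedTargets, FlowField

__all__ = ["save_fields", "load_fields"]

_FLOW_NAMES = {2: ["flow_y", "flow_x"], 3: ["flow_z", "flow_y", "flow_x"]}


def save_fields(path, phi, flow, boundary, encoded: bool = False) -> None:
    """Write (distance, flow, boundary) as a (C, ...) float32 TIFF + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    phi_arr = phi.phi if isinstance(phi, DistanceField) else np.asarray(phi)
    comps = flow.components if isinstance(flow, FlowField) else np.asarray(flow)
    bnd = boundary.indicator if isinstance(boundary, BoundaryMap) else np.asarray(boundary)
    dim = phi_arr.ndim
    stack = np.concatenate(
        [comps, phi_arr[None], bnd.astype(np.float64)[None]], axis=0
    ).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "channels": _FLOW_NAMES[dim] + ["distance", "boundary"],
        "dim": dim,
        "convention": "encoded" if encoded else "raw",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_fields(path):
    """Read a field stack; returns (phi, FlowField, boundary, convention)."""
    path = Path(path)
    stack = tifffile.imread(path).astype(np.float64)
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        dim = int(meta["dim"])
        convention = meta.get("convention", "raw")
    else:
        dim = stack.ndim - 1
        convention = "raw"
    n_flow = dim
    comps = stack[:n_flow]
    phi = stack[n_flow]
    bnd = stack[n_flow + 1]
    return DistanceField(phi), FlowField(comps), BoundaryMap(bnd), convention
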