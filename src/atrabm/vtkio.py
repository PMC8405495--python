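"""Cell-map and field snapshots as legacy-VTK ASCII image data.

The files open directly in ParaView: one STRUCTURED_POINTS dataset per
snapshot with an integer ``cell_state`` array (state-coded sites, -1 for
empty) and any number of named scalar field arrays (oxygen %, drug µM).
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np

from .lattice import EMPTY, Lattice


def write_snapshot(path: str, lat: Lattice, pop=None,
                   fields: Optional[Mapping[str, np.ndarray]] = None) -> None:
    """Write one lattice snapshot.  With ``pop`` given, sites carry the
    occupying agent's cell-cycle state code; otherwise just occupancy."""
    size = lat.size
    ids = lat.occupancy
    state_map = np.full((size, size), EMPTY, dtype=np.int64)
    occ = ids != EMPTY
    if pop is not None and occ.any():
        state_map[occ] = pop.state[ids[occ]]
    else:
        state_map[occ] = 1

    spacing = lat.spacing_cm or 1.0
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("atrabm lattice snapshot\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {size} {size} 1\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {spacing} {spacing} 1\n")
        fh.write(f"POINT_DATA {size * size}\n")
        _write_array(fh, "cell_state", state_map, "int")
        for name, arr in (fields or {}).items():
            _write_array(fh, name, np.asarray(arr, dtype=float), "float")


def _write_array(fh, name: str, arr: np.ndarray, kind: str) -> None:
    fh.write(f"SCALARS {name} {kind} 1\n")
    fh.write("LOOKUP_TABLE default\n")
    flat = arr.ravel(order="C")
    fmt = (lambda x: str(int(x))) if kind == "int" else (lambda x: f"{x:.6g}")
    for start in range(0, flat.size, 9):
        fh.write(" ".join(fmt(v) for v in flat[start:start + 9]) + "\n")
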