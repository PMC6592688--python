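"""Serialization: VTK legacy / PLY mesh export, energy CSV, JSON records."""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np

from .geometry import Region, TetMesh, surface_triangles

__all__ = [
    "write_vtk_legacy",
    "write_ply_surface",
    "write_energy_csv",
    "write_json",
    "config_hash",
]


def write_vtk_legacy(path, mesh: TetMesh, state=None, point_data=None, cell_data=None):
    """ASCII VTK legacy unstructured grid with region and node-set labels.

    When ``state`` is given, nodes are written at their deformed positions
    and the displacement field is attached as point data.
    """
    path = Path(path)
    points = state.x if state is not None else mesh.node_positions
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    if state is not None:
        point_data.setdefault("displacement", state.x - mesh.node_positions)
    for name, nodes in mesh.node_sets.items():
        flag = np.zeros(mesh.n_nodes, dtype=np.int32)
        flag[nodes] = 1
        point_data.setdefault(f"set_{name}", flag)
    cell_data.setdefault("region", mesh.region_of_tet.astype(np.int32))

    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfrillsim mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        np.savetxt(fh, points, fmt="%.10g")
        tets = mesh.tets
        fh.write(f"CELLS {len(tets)} {5 * len(tets)}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(len(tets), 4, dtype=np.int64), tets]),
            fmt="%d",
        )
        fh.write(f"CELL_TYPES {len(tets)}\n")
        np.savetxt(fh, np.full(len(tets), 10, dtype=np.int64), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {len(points)}\n")
            _write_arrays(fh, point_data)
        if cell_data:
            fh.write(f"CELL_DATA {len(tets)}\n")
            _write_arrays(fh, cell_data)
    return path


def _write_arrays(fh, arrays: dict):
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        if arr.ndim == 1:
            typ = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            fh.write(f"SCALARS {name} {typ} 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%d" if typ == "int" else "%.10g")
        else:
            fh.write(f"VECTORS {name} double\n")
            np.savetxt(fh, arr, fmt="%.10g")


def write_ply_surface(path, mesh: TetMesh, state=None, node_set="ANTERIOR_SURFACE"):
    """Anterior-surface triangulation as ASCII PLY (via trimesh)."""
    import trimesh

    tris = surface_triangles(mesh, node_set)
    points = state.x if state is not None else mesh.node_positions
    used = np.unique(tris)
    remap = np.full(mesh.n_nodes, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    tm = trimesh.Trimesh(vertices=points[used], faces=remap[tris], process=False)
    Path(path).write_bytes(tm.export(file_type="ply", encoding="ascii"))
    return Path(path)


def write_energy_csv(path, energy_history):
    """(iteration, energy, max_step_displacement) rows."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "energy", "max_step_displacement"])
        for row in energy_history:
            w.writerow(list(row))
    return path


def write_json(path, payload: dict):
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_coerce))
    return path


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Region):
        return obj.name
    raise TypeError(f"cannot serialize {type(obj)}")


def config_hash(config: dict) -> str:
    """Stable short hash of a (JSON-serialisable) configuration snapshot."""
    blob = json.dumps(config, sort_keys=True, default=_coerce).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
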