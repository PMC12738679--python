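"""Legacy-VTK (ASCII) and CSV export of meshes, parameter and solution fields.

Scalars are written as VTK SCALARS, 2D vectors as VECTORS (z padded),
symmetric 2x2/3x3 tensors as 6-component FIELD arrays in the order
xx, yy, zz, xy, xz, yz.  Every VTK file gets a CSV mirror keyed by cell
(or point) id so results stay machine-readable without a VTK stack.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

__all__ = ["write_vtk_mesh", "write_cell_data_csv", "write_point_data_csv", "tensor_to_sym6"]


def tensor_to_sym6(T) -> np.ndarray:
    """(n, d, d) symmetric tensors -> (n, 6) rows xx, yy, zz, xy, xz, yz."""
    T = np.asarray(T, float)
    n, d = T.shape[0], T.shape[1]
    out = np.zeros((n, 6))
    out[:, 0] = T[:, 0, 0]
    out[:, 1] = T[:, 1, 1]
    out[:, 3] = T[:, 0, 1]
    if d > 2:
        out[:, 2] = T[:, 2, 2]
        out[:, 4] = T[:, 0, 2]
        out[:, 5] = T[:, 1, 2]
    return out


def _write_array(fh, a, per_line=1):
    a = np.atleast_2d(np.asarray(a, float))
    for row in a.reshape(-1, a.shape[-1]) if a.ndim > 1 else a:
        fh.write(" ".join(f"{x:.10g}" for x in np.atleast_1d(row)) + "\n")


def _classify(name, arr, n_expected):
    arr = np.asarray(arr, float)
    if arr.shape[0] != n_expected:
        raise ValueError(f"field {name!r}: expected leading size {n_expected}")
    if arr.ndim == 1:
        return "scalar", arr
    if arr.ndim == 2 and arr.shape[1] in (2, 3):
        v = np.zeros((len(arr), 3))
        v[:, : arr.shape[1]] = arr
        return "vector", v
    if arr.ndim == 3 and arr.shape[1] == arr.shape[2]:
        return "tensor6", tensor_to_sym6(arr)
    raise ValueError(f"field {name!r}: unsupported shape {arr.shape}")


def _write_data_block(fh, fields, n, kind):
    fh.write(f"{kind} {n}\n")
    classified = {k: _classify(k, v, n) for k, v in fields.items()}
    tensors = {k: v for k, v in classified.items() if v[0] == "tensor6"}
    for name, (tag, arr) in classified.items():
        if tag == "scalar":
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for x in arr:
                fh.write(f"{x:.10g}\n")
        elif tag == "vector":
            fh.write(f"VECTORS {name} float\n")
            _write_array(fh, arr)
    if tensors:
        fh.write(f"FIELD tensors {len(tensors)}\n")
        for name, (_, arr) in tensors.items():
            fh.write(f"{name} 6 {n} float\n")
            _write_array(fh, arr)


def write_vtk_mesh(path, mesh, point_data=None, cell_data=None, title="perfusim fields"):
    """Write a triangle mesh with attached fields as legacy ASCII VTK."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title[:255] + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        pts3 = np.hstack([mesh.vertices, np.zeros((mesh.n_vertices, 1))])
        _write_array(fh, pts3)
        fh.write(f"CELLS {mesh.n_cells} {4 * mesh.n_cells}\n")
        for c in mesh.cells:
            fh.write(f"3 {c[0]} {c[1]} {c[2]}\n")
        fh.write(f"CELL_TYPES {mesh.n_cells}\n")
        fh.write("\n".join(["5"] * mesh.n_cells) + "\n")
        if point_data:
            _write_data_block(fh, point_data, mesh.n_vertices, "POINT_DATA")
        if cell_data:
            _write_data_block(fh, cell_data, mesh.n_cells, "CELL_DATA")
    return path


def _flatten_fields(fields, n):
    cols, header = [], ["id"]
    for name, arr in fields.items():
        tag, a = _classify(name, arr, n)
        if tag == "scalar":
            header.append(name)
            cols.append(a[:, None])
        elif tag == "vector":
            header += [f"{name}_x", f"{name}_y", f"{name}_z"]
            cols.append(a)
        else:
            header += [f"{name}_{c}" for c in ("xx", "yy", "zz", "xy", "xz", "yz")]
            cols.append(a)
    return header, np.hstack(cols) if cols else np.empty((n, 0))


def _write_csv(path, fields, n):
    header, data = _flatten_fields(fields, n)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for i in range(n):
            w.writerow([i] + [f"{x:.12g}" for x in data[i]])
    return Path(path)


def write_cell_data_csv(path, mesh, cell_data):
    """CSV mirror of per-cell fields, keyed by cell id."""
    return _write_csv(path, cell_data, mesh.n_cells)


def write_point_data_csv(path, mesh, point_data):
    """CSV mirror of per-vertex fields, keyed by point id."""
    return _write_csv(path, point_data, mesh.n_vertices)
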