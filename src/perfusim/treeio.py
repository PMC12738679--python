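"""Tree file I/O: CSV pair, JSON mirror, and legacy-VTK polydata.

Formats
-------
``csv-pair``
    A directory with ``nodes.csv`` (id,x,y,z,kind), ``segments.csv``
    (id,u,v,radius,flow) and ``meta.json`` (scalar tree parameters).
    Segment lengths are never stored; they are recomputed from node
    positions on load, so position/length consistency holds by
    construction.
``json``
    A single file mirroring the same field names.
``vtk``
    Legacy ASCII polydata with one line cell per segment and per-segment
    cell data (radius, flow, and optionally a compartment index), meant
    for visualization in ParaView.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .tree import TreeStructureError, VascularTree

__all__ = ["write_tree", "read_tree"]

_FORMATS = ("csv-pair", "json", "vtk")


class TreeParseError(ValueError):
    pass


def _meta(tree: VascularTree) -> dict:
    return {
        "q_perf": tree.q_perf,
        "p_root": tree.p_root,
        "m_b": tree.m_b,
        "eta": tree.eta,
        "role": tree.role,
    }


def _node_kinds(tree: VascularTree) -> np.ndarray:
    kinds = np.full(tree.n_nodes, "internal", dtype=object)
    kinds[tree.root] = "root"
    kinds[tree.leaves] = "leaf"
    return kinds


def write_tree(tree: VascularTree, path: str, format: str = "csv-pair",
               compartment_index=None) -> None:
    """Write a tree; see module docstring for the schemas."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}, expected one of {_FORMATS}")
    if format == "csv-pair":
        os.makedirs(path, exist_ok=True)
        nodes = pd.DataFrame(
            {
                "id": np.arange(tree.n_nodes),
                "x": tree.positions[:, 0],
                "y": tree.positions[:, 1],
                "z": tree.positions[:, 2],
                "kind": _node_kinds(tree),
            }
        )
        segs = pd.DataFrame(
            {
                "id": np.arange(tree.n_segments),
                "u": tree.proximal,
                "v": tree.distal,
                "radius": tree.radii,
                "flow": tree.flows,
            }
        )
        if compartment_index is not None:
            segs["compartment"] = np.asarray(compartment_index, dtype=np.int64)
        nodes.to_csv(os.path.join(path, "nodes.csv"), index=False)
        segs.to_csv(os.path.join(path, "segments.csv"), index=False)
        with open(os.path.join(path, "meta.json"), "w") as fh:
            json.dump(_meta(tree), fh, indent=1)
    elif format == "json":
        doc = {
            "meta": _meta(tree),
            "nodes": {
                "id": list(range(tree.n_nodes)),
                "x": tree.positions[:, 0].tolist(),
                "y": tree.positions[:, 1].tolist(),
                "z": tree.positions[:, 2].tolist(),
                "kind": _node_kinds(tree).tolist(),
            },
            "segments": {
                "id": list(range(tree.n_segments)),
                "u": tree.proximal.tolist(),
                "v": tree.distal.tolist(),
                "radius": tree.radii.tolist(),
                "flow": tree.flows.tolist(),
            },
        }
        if compartment_index is not None:
            doc["segments"]["compartment"] = [
                int(c) for c in np.asarray(compartment_index)
            ]
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:  # vtk polydata
        lines = [
            "# vtk DataFile Version 3.0",
            json.dumps(_meta(tree)),
            "ASCII",
            "DATASET POLYDATA",
            f"POINTS {tree.n_nodes} double",
        ]
        for p in tree.positions:
            lines.append(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}")
        m = tree.n_segments
        lines.append(f"LINES {m} {3 * m}")
        for u, v in zip(tree.proximal, tree.distal):
            lines.append(f"2 {u} {v}")
        lines.append(f"CELL_DATA {m}")
        fields = {"radius": tree.radii, "flow": tree.flows}
        if compartment_index is not None:
            fields["compartment"] = np.asarray(compartment_index, float)
        for name, values in fields.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{x:.17g}" for x in values)
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _build_tree(node_ids, pos, seg_u, seg_v, radius, flow, meta) -> VascularTree:
    index = {int(i): k for k, i in enumerate(node_ids)}
    n = len(node_ids)
    parent = np.full(n, -1, dtype=np.int64)
    radii = np.full(n, np.nan)
    flows = np.full(n, np.nan)
    for row, (u, v) in enumerate(zip(seg_u, seg_v)):
        if int(u) not in index or int(v) not in index:
            raise TreeParseError(f"segment row {row}: unknown node reference ({u},{v})")
        vi = index[int(v)]
        if parent[vi] != -1:
            raise TreeParseError(f"segment row {row}: node {v} has multiple parents")
        parent[vi] = index[int(u)]
        radii[vi] = radius[row]
        flows[vi] = flow[row]
    try:
        tree = VascularTree(pos, parent, **meta)
    except TreeStructureError as exc:
        raise TreeParseError(str(exc)) from exc
    tree.radii = radii[tree.distal]
    tree.flows = flows[tree.distal]
    return tree


def read_tree(path: str, format: str = "csv-pair") -> VascularTree:
    """Read a tree written by :func:`write_tree`.

    Raises :class:`TreeParseError` naming the offending row on malformed
    parent references or multi-parent nodes.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}, expected one of {_FORMATS}")
    if format == "csv-pair":
        nodes = pd.read_csv(os.path.join(path, "nodes.csv"))
        segs = pd.read_csv(os.path.join(path, "segments.csv"))
        meta_path = os.path.join(path, "meta.json")
        meta = json.load(open(meta_path)) if os.path.exists(meta_path) else {}
        pos = nodes[["x", "y", "z"]].to_numpy()
        return _build_tree(
            nodes["id"].to_numpy(), pos,
            segs["u"].to_numpy(), segs["v"].to_numpy(),
            segs["radius"].to_numpy(float), segs["flow"].to_numpy(float), meta,
        )
    if format == "json":
        doc = json.load(open(path))
        nd, sg = doc["nodes"], doc["segments"]
        pos = np.column_stack([nd["x"], nd["y"], nd["z"]])
        return _build_tree(
            np.asarray(nd["id"]), pos,
            np.asarray(sg["u"]), np.asarray(sg["v"]),
            np.asarray(sg["radius"], float), np.asarray(sg["flow"], float),
            doc.get("meta", {}),
        )
    return _read_vtk(path)


def _read_vtk(path: str) -> VascularTree:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    try:
        meta = json.loads(lines[1])
    except json.JSONDecodeError:
        meta = {}
    i = lines.index(next(ln for ln in lines if ln.startswith("POINTS")))
    n = int(lines[i].split()[1])
    pos = np.array([[float(x) for x in lines[i + 1 + k].split()] for k in range(n)])
    j = i + 1 + n
    if not lines[j].startswith("LINES"):
        raise TreeParseError("expected LINES block after POINTS")
    m = int(lines[j].split()[1])
    conn = np.array([[int(x) for x in lines[j + 1 + k].split()[1:]] for k in range(m)])
    data = {}
    k = j + 1 + m
    while k < len(lines):
        if lines[k].startswith("SCALARS"):
            name = lines[k].split()[1]
            vals = [float(lines[k + 2 + t]) for t in range(m)]
            data[name] = np.asarray(vals)
            k += 2 + m
        else:
            k += 1
    return _build_tree(
        np.arange(n), pos, conn[:, 0], conn[:, 1],
        data.get("radius", np.full(m, np.nan)),
        data.get("flow", np.full(m, np.nan)), meta,
    )
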