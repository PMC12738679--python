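import numpy as np
import pytest

from perfusim import (
    TriMesh,
    disk_mesh,
    read_msh,
    rectangle_mesh,
    tensor_to_sym6,
    write_cell_data_csv,
    write_point_data_csv,
    write_vtk_mesh,
)


def test_rectangle_mesh_area_and_counts():
    mesh = rectangle_mesh((0.0, 2.0, -1.0, 1.0), 4, 5)
    assert mesh.n_vertices == 5 * 6
    assert mesh.n_cells == 2 * 4 * 5
    assert mesh.total_volume() == pytest.approx(4.0, rel=1e-12)
    assert (mesh.cell_areas() > 0).all()


def test_disk_mesh_covers_disk():
    mesh = disk_mesh(radius=2.0, edge_length=0.4)
    # Delaunay of a convex point cloud covers the convex hull: area
    # approaches pi R^2 from below as the boundary polygon refines
    assert mesh.total_volume() < np.pi * 4.0
    assert mesh.total_volume() > 0.97 * np.pi * 4.0
    q = mesh.quality()
    assert q["min_angle_deg"] > 10.0
    with pytest.raises(ValueError):
        disk_mesh(-1.0, 0.1)


def test_mesh_orientation_fixed_and_degenerate_rejected():
    # clockwise triangle gets flipped, not rejected
    mesh = TriMesh([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0]], [[0, 1, 2]])
    assert mesh.cell_areas()[0] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        TriMesh([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]], [[0, 1, 2]])


def test_contains():
    mesh = rectangle_mesh((0.0, 1.0, 0.0, 1.0), 6, 6)
    pts = np.array([[0.5, 0.5], [0.01, 0.99], [1.5, 0.5], [-0.1, 0.2]])
    assert mesh.contains(pts).tolist() == [True, True, False, False]


def test_edges_unique_count():
    mesh = rectangle_mesh((0.0, 1.0, 0.0, 1.0), 2, 2)
    edges, cell_edges = mesh.edges()
    # Euler: E = V + C - 1 for a planar triangulated disk
    assert len(edges) == mesh.n_vertices + mesh.n_cells - 1
    assert cell_edges.shape == (mesh.n_cells, 3)


def _write_msh(path, verts, tris, extra_elements=()):
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(len(verts))]
    for i, (x, y) in enumerate(verts, start=1):
        lines.append(f"{i} {x} {y} 0")
    lines += ["$EndNodes", "$Elements", str(len(tris) + len(extra_elements))]
    eid = 1
    for el in extra_elements:
        lines.append(f"{eid} {el}")
        eid += 1
    for t in tris:
        lines.append(f"{eid} 2 2 0 1 {t[0]} {t[1]} {t[2]}")
        eid += 1
    lines += ["$EndElements"]
    path.write_text("\n".join(lines) + "\n")


def test_read_msh_roundtrip(tmp_path):
    verts = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]
    tris = [(1, 2, 3), (1, 3, 4)]
    p = tmp_path / "square.msh"
    # include a boundary line element (type 1) that must be skipped
    _write_msh(p, verts, tris, extra_elements=["1 2 0 1 1 2"])
    mesh = read_msh(str(p))
    assert mesh.n_vertices == 4
    assert mesh.n_cells == 2
    assert mesh.total_volume() == pytest.approx(1.0)


def test_read_msh_errors(tmp_path):
    p = tmp_path / "bad.msh"
    p.write_text("not a mesh\n")
    with pytest.raises(ValueError):
        read_msh(str(p))
    q = tmp_path / "notri.msh"
    _write_msh(q, [(0.0, 0.0), (1.0, 0.0)], [], extra_elements=["1 2 0 1 1 2"])
    with pytest.raises(ValueError):
        read_msh(str(q))


def test_tensor_to_sym6():
    T = np.array([[[1.0, 2.0], [2.0, 3.0]]])
    row = tensor_to_sym6(T)[0]
    assert row.tolist() == [1.0, 3.0, 0.0, 2.0, 0.0, 0.0]


def test_vtk_writer_and_csv_mirror(tmp_path):
    mesh = rectangle_mesh((0.0, 1.0, 0.0, 1.0), 2, 2)
    n = mesh.n_cells
    K = np.broadcast_to(np.diag([1.0, 2.0]), (n, 2, 2)).copy()
    vel = np.random.default_rng(0).random((n, 2))
    pressure = np.arange(mesh.n_vertices, dtype=float)
    vtk = write_vtk_mesh(
        tmp_path / "out.vtk",
        mesh,
        point_data={"pressure": pressure},
        cell_data={"K": K, "velocity": vel, "beta": np.ones(n)},
    )
    text = vtk.read_text()
    assert "DATASET UNSTRUCTURED_GRID" in text
    assert f"POINT_DATA {mesh.n_vertices}" in text
    assert f"CELL_DATA {n}" in text
    assert "SCALARS beta" in text and "VECTORS velocity" in text
    assert "K 6" in text  # tensor written as a 6-component FIELD array

    csvp = write_cell_data_csv(tmp_path / "cells.csv", mesh, {"K": K, "beta": np.ones(n)})
    import pandas as pd

    df = pd.read_csv(csvp)
    assert list(df.columns)[:2] == ["id", "K_xx"]
    assert np.allclose(df["K_yy"], 2.0)
    assert len(df) == n

    dfp = pd.read_csv(
        write_point_data_csv(tmp_path / "pts.csv", mesh, {"pressure": pressure})
    )
    assert np.allclose(dfp["pressure"], pressure)

    with pytest.raises(ValueError):
        write_cell_data_csv(tmp_path / "bad.csv", mesh, {"beta": np.ones(n + 1)})
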