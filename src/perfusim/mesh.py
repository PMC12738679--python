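"""Triangle meshes: built-in disk/rectangle meshers and a Gmsh MSH v2 reader.

Meshes are plain arrays: ``vertices`` (n, 2) in mm and ``cells`` (m, 3)
vertex indices, counter-clockwise.  Quadratic (P2) degrees of freedom are
managed by the FEM layer, not here.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = ["TriMesh", "disk_mesh", "rectangle_mesh", "read_msh"]


def _cross2(a, b):
    """z-component of the cross product of stacks of 2D vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


class TriMesh:
    def __init__(self, vertices, cells):
        self.vertices = np.asarray(vertices, dtype=float)
        self.cells = np.asarray(cells, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (n, 2)")
        if self.cells.ndim != 2 or self.cells.shape[1] != 3:
            raise ValueError("cells must be (m, 3)")
        self._fix_orientation()
        if np.any(self.cell_areas() <= 0):
            raise ValueError("mesh contains degenerate (zero-area) cells")
        self._centroid_tree = None

    def _fix_orientation(self):
        v = self.vertices
        c = self.cells
        cross = _cross2(v[c[:, 1]] - v[c[:, 0]], v[c[:, 2]] - v[c[:, 0]])
        flip = cross < 0
        if np.any(flip):
            self.cells[flip] = self.cells[flip][:, [0, 2, 1]]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_areas(self) -> np.ndarray:
        v = self.vertices
        c = self.cells
        return 0.5 * _cross2(v[c[:, 1]] - v[c[:, 0]], v[c[:, 2]] - v[c[:, 0]])

    def centroids(self) -> np.ndarray:
        return self.vertices[self.cells].mean(axis=1)

    def total_volume(self) -> float:
        return float(self.cell_areas().sum())

    def bounding_box(self) -> np.ndarray:
        return np.column_stack(
            [self.vertices.min(axis=0), self.vertices.max(axis=0)]
        )

    def contains(self, points, tol: float = 1e-12) -> np.ndarray:
        """Point-in-mesh test via barycentric coordinates of nearby cells."""
        pts = np.atleast_2d(np.asarray(points, float))[:, :2]
        if self._centroid_tree is None:
            self._centroid_tree = cKDTree(self.centroids())
        k = min(16, self.n_cells)
        _, cand = self._centroid_tree.query(pts, k=k)
        cand = np.atleast_2d(cand)
        out = np.zeros(len(pts), dtype=bool)
        v = self.vertices
        for col in range(cand.shape[1]):
            rem = ~out
            if not np.any(rem):
                break
            cells = self.cells[cand[rem, col]]
            p = pts[rem]
            a, b, c = v[cells[:, 0]], v[cells[:, 1]], v[cells[:, 2]]
            det = _cross2(b - a, c - a)
            l1 = _cross2(b - p, c - p) / det
            l2 = _cross2(c - p, a - p) / det
            l3 = 1.0 - l1 - l2
            inside = (l1 >= -tol) & (l2 >= -tol) & (l3 >= -tol)
            idx = np.flatnonzero(rem)
            out[idx[inside]] = True
        return out

    def edges(self):
        """Unique undirected edges and per-cell edge indices (for P2 dofs)."""
        c = self.cells
        e = np.concatenate([c[:, [0, 1]], c[:, [1, 2]], c[:, [2, 0]]])
        e_sorted = np.sort(e, axis=1)
        uniq, inv = np.unique(e_sorted, axis=0, return_inverse=True)
        cell_edges = inv.reshape(3, -1).T  # columns: edge opposite to local v2, v0, v1
        return uniq, cell_edges

    def quality(self) -> dict:
        """Min angle (deg) and area ratio; a coarse sanity report for loaded meshes."""
        v = self.vertices[self.cells]
        angles = []
        for i in range(3):
            a = v[:, (i + 1) % 3] - v[:, i]
            b = v[:, (i + 2) % 3] - v[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        areas = self.cell_areas()
        return {
            "min_angle_deg": float(np.min(angles)),
            "area_ratio": float(areas.max() / areas.min()),
            "n_cells": self.n_cells,
        }


def disk_mesh(radius: float, edge_length: float, center=(0.0, 0.0)) -> TriMesh:
    """Unstructured-looking disk triangulation from concentric rings + Delaunay."""
    if radius <= 0 or edge_length <= 0:
        raise ValueError("radius and edge_length must be positive")
    center = np.asarray(center, float)
    n_rings = max(1, int(round(radius / edge_length)))
    pts = [center]
    for k in range(1, n_rings + 1):
        r = radius * k / n_rings
        n_theta = max(6, int(round(2 * np.pi * r / edge_length)))
        # stagger alternate rings for better-shaped triangles
        offset = (k % 2) * np.pi / n_theta
        theta = offset + np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        pts.append(center + r * np.column_stack([np.cos(theta), np.sin(theta)]))
    pts = np.vstack(pts)
    tri = Delaunay(pts)
    return TriMesh(pts, tri.simplices)


def rectangle_mesh(bounds, nx: int, ny: int) -> TriMesh:
    """Structured crossed triangulation of a rectangle.

    ``bounds = (xmin, xmax, ymin, ymax)``; each of the nx*ny quads is split
    into two triangles.
    """
    xmin, xmax, ymin, ymax = bounds
    xs = np.linspace(xmin, xmax, nx + 1)
    ys = np.linspace(ymin, ymax, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel()])

    def vid(i, j):
        return i * (ny + 1) + j

    cells = []
    for i in range(nx):
        for j in range(ny):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            if (i + j) % 2 == 0:
                cells += [[a, b, c], [a, c, d]]
            else:
                cells += [[a, b, d], [b, c, d]]
    return TriMesh(verts, np.asarray(cells))


def read_msh(path: str) -> TriMesh:
    """Read a Gmsh MSH 2.2 ASCII file (triangles only)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        i_n = lines.index("$Nodes")
        i_e = lines.index("$Elements")
    except ValueError as exc:
        raise ValueError("not a MSH 2.2 ASCII file (missing $Nodes/$Elements)") from exc
    n = int(lines[i_n + 1])
    ids = np.empty(n, dtype=np.int64)
    verts = np.empty((n, 2))
    for k in range(n):
        parts = lines[i_n + 2 + k].split()
        ids[k] = int(parts[0])
        verts[k] = [float(parts[1]), float(parts[2])]
    remap = {int(i): k for k, i in enumerate(ids)}
    m = int(lines[i_e + 1])
    cells = []
    for k in range(m):
        parts = lines[i_e + 2 + k].split()
        etype = int(parts[1])
        if etype != 2:  # skip points/lines, keep 3-node triangles
            continue
        ntags = int(parts[2])
        conn = parts[3 + ntags : 6 + ntags]
        cells.append([remap[int(c)] for c in conn])
    if not cells:
        raise ValueError("MSH file contains no triangles")
    return TriMesh(verts, np.asarray(cells))
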