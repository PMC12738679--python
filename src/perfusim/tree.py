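"""Discrete vascular trees as Poiseuille flow networks.

A vascular tree is a rooted out-tree of rigid straight cylindrical
segments.  Blood is incompressible and Newtonian in the laminar regime,
so each segment obeys Poiseuille's law

    dp_a = zeta_a * Q_a,       zeta_a = 8 eta_a l_a / (pi r_a^4),

flows satisfy Kirchhoff balance at every branching node, and the given
root (perfusion) flow is distributed homogeneously over all terminals,
Q_term = Q_perf / N_term.

The tree is stored array-backed: node positions plus a parent index per
node.  There is exactly one segment per non-root node (the segment whose
distal node it is), which makes the rooted-out-tree invariant structural
rather than something to check after every mutation.  Draining trees use
the same storage convention (flow directed root -> leaf) with a
``role`` flag; the physical flow direction and the pressure sign are
interpreted through the role.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VesselNode",
    "VesselSegment",
    "VascularTree",
    "VascularForest",
    "TreeStructureError",
    "optimal_radius_coefficient",
    "compute_flows",
    "optimal_radii",
    "tree_cost",
    "node_pressures",
]


class TreeStructureError(ValueError):
    """Raised when a node/parent table does not describe a rooted out-tree."""


@dataclass(frozen=True)
class VesselNode:
    """Read-only view of one node of a :class:`VascularTree`."""

    id: int
    position: np.ndarray
    kind: str  # {"root", "internal", "leaf"}


@dataclass(frozen=True)
class VesselSegment:
    """Read-only view of one segment (= one non-root node) of a tree."""

    id: int
    proximal: int
    distal: int
    length: float
    radius: float
    flow: float
    viscosity: float

    @property
    def resistance(self) -> float:
        return 8.0 * self.viscosity * self.length / (np.pi * self.radius**4)

    @property
    def pressure_drop(self) -> float:
        return self.resistance * self.flow


def optimal_radius_coefficient(eta: float, m_b: float) -> float:
    """Prefactor c of the power-optimal radius law r = c * Q^(1/3).

    Minimizing the per-segment power w(r) = m_b pi r^2 + 8 eta Q^2/(pi r^4)
    gives r^6 = 16 eta Q^2 / (m_b pi^2).
    """
    return (16.0 * eta / (m_b * np.pi**2)) ** (1.0 / 6.0)


class VascularTree:
    """Array-backed rooted out-tree of cylindrical vessel segments.

    Parameters
    ----------
    positions : (n_nodes, 3) array
        Node coordinates in mm.  2D problems use z = 0.
    parent : (n_nodes,) int array
        Parent node index per node; -1 marks the single root.
    q_perf : float
        Root (perfusion) flow in mm^3/s.
    p_root : float
        Root pressure in kg mm^-1 s^-2.
    m_b : float
        Metabolic demand factor in uW/mm^3.
    eta : float
        Dynamic blood viscosity in kg mm^-1 s^-1 (default 3.6 cP).
    role : {"supplying", "draining"}
        Physical interpretation flag; storage is identical for both.

    Segment ``i`` runs from ``parent[distal[i]]`` to ``distal[i]`` where
    ``distal`` enumerates all non-root nodes in node order.
    """

    def __init__(
        self,
        positions,
        parent,
        *,
        q_perf: float = 1.0,
        p_root: float = 0.0,
        m_b: float = 0.6,
        eta: float = 3.6e-6,
        role: str = "supplying",
        radii=None,
        flows=None,
        viscosities=None,
    ):
        self.positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if self.positions.shape[1] == 2:
            self.positions = np.hstack(
                [self.positions, np.zeros((len(self.positions), 1))]
            )
        self.parent = np.asarray(parent, dtype=np.int64)
        if role not in ("supplying", "draining"):
            raise ValueError(f"unknown tree role {role!r}")
        self.q_perf = float(q_perf)
        self.p_root = float(p_root)
        self.m_b = float(m_b)
        self.eta = float(eta)
        self.role = role

        self._validate_structure()
        m = self.n_segments
        self.radii = (
            np.full(m, np.nan) if radii is None else np.asarray(radii, float).copy()
        )
        self.flows = (
            np.full(m, np.nan) if flows is None else np.asarray(flows, float).copy()
        )
        self.viscosities = (
            np.full(m, self.eta)
            if viscosities is None
            else np.asarray(viscosities, float).copy()
        )

    # -- structure ---------------------------------------------------------

    def _validate_structure(self) -> None:
        n = len(self.parent)
        if self.positions.shape[0] != n:
            raise TreeStructureError("positions/parent length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeStructureError(f"expected exactly one root, got {len(roots)}")
        self.root = int(roots[0])
        if np.any(self.parent >= n):
            raise TreeStructureError("parent index out of range")
        # depth computation doubles as acyclicity / connectivity check
        depth = np.full(n, -1, dtype=np.int64)
        depth[self.root] = 0
        order = [self.root]
        children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                children[p].append(v)
        head = 0
        while head < len(order):
            u = order[head]
            head += 1
            for v in children[u]:
                depth[v] = depth[u] + 1
                order.append(v)
        if len(order) != n:
            raise TreeStructureError("graph contains a cycle or unreachable nodes")
        self.depth = depth
        self._topo_order = np.asarray(order, dtype=np.int64)
        self._children = children
        # segment i <-> non-root node distal[i]
        self.distal = np.flatnonzero(self.parent >= 0)
        self._seg_of_node = np.full(n, -1, dtype=np.int64)
        self._seg_of_node[self.distal] = np.arange(len(self.distal))

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_segments(self) -> int:
        return len(self.distal)

    @property
    def dim(self) -> int:
        return 2 if np.allclose(self.positions[:, 2], 0.0) else 3

    @property
    def leaves(self) -> np.ndarray:
        n_children = np.bincount(
            self.parent[self.parent >= 0], minlength=self.n_nodes
        )
        return np.flatnonzero((n_children == 0) & (np.arange(self.n_nodes) != self.root))

    @property
    def n_term(self) -> int:
        return len(self.leaves)

    @property
    def q_term(self) -> float:
        return self.q_perf / self.n_term

    @property
    def proximal(self) -> np.ndarray:
        """Proximal node index per segment."""
        return self.parent[self.distal]

    @property
    def lengths(self) -> np.ndarray:
        """Segment lengths, always recomputed from node positions."""
        d = self.positions[self.distal] - self.positions[self.proximal]
        return np.linalg.norm(d, axis=1)

    @property
    def orientations(self) -> np.ndarray:
        d = self.positions[self.distal] - self.positions[self.proximal]
        return d / np.linalg.norm(d, axis=1)[:, None]

    @property
    def resistances(self) -> np.ndarray:
        return 8.0 * self.viscosities * self.lengths / (np.pi * self.radii**4)

    @property
    def pressure_drops(self) -> np.ndarray:
        return self.resistances * self.flows

    def segment_of_node(self, v: int) -> int:
        """Index of the segment whose distal node is ``v`` (-1 for the root)."""
        return int(self._seg_of_node[v])

    def node(self, i: int) -> VesselNode:
        if i == self.root:
            kind = "root"
        elif i in set(self.leaves):
            kind = "leaf"
        else:
            kind = "internal"
        return VesselNode(id=i, position=self.positions[i].copy(), kind=kind)

    def segment(self, i: int) -> VesselSegment:
        v = int(self.distal[i])
        return VesselSegment(
            id=i,
            proximal=int(self.parent[v]),
            distal=v,
            length=float(self.lengths[i]),
            radius=float(self.radii[i]),
            flow=float(self.flows[i]),
            viscosity=float(self.viscosities[i]),
        )

    def copy(self) -> "VascularTree":
        return VascularTree(
            self.positions.copy(),
            self.parent.copy(),
            q_perf=self.q_perf,
            p_root=self.p_root,
            m_b=self.m_b,
            eta=self.eta,
            role=self.role,
            radii=self.radii,
            flows=self.flows,
            viscosities=self.viscosities,
        )

    # -- network physics ---------------------------------------------------

    def kirchhoff_residuals(self) -> np.ndarray:
        """Flow imbalance (inflow - outflow) at every interior node."""
        n = self.n_nodes
        inflow = np.zeros(n)
        outflow = np.zeros(n)
        np.add.at(inflow, self.distal, self.flows)
        np.add.at(outflow, self.proximal, self.flows)
        interior = np.ones(n, dtype=bool)
        interior[self.root] = False
        interior[self.leaves] = False
        return (inflow - outflow)[interior]


def compute_flows(tree: VascularTree) -> VascularTree:
    """Propagate the homogeneous terminal flow up the tree (Kirchhoff).

    Every leaf segment carries Q_term = Q_perf / N_term; every interior
    segment carries the sum of its children's flows, so the root segment
    carries Q_perf.  Modifies ``tree`` in place and returns it.
    """
    n = tree.n_nodes
    leaf_count = np.zeros(n)
    leaf_count[tree.leaves] = 1.0
    # accumulate leaf counts bottom-up along the topological order
    for v in tree._topo_order[::-1]:
        p = tree.parent[v]
        if p >= 0:
            leaf_count[p] += leaf_count[v]
    tree.flows = leaf_count[tree.distal] * tree.q_term
    return tree


def optimal_radii(tree: VascularTree) -> VascularTree:
    """Set every radius to its power-optimal value r = (16 eta/(m_b pi^2))^(1/6) Q^(1/3)."""
    if np.any(~np.isfinite(tree.flows)) or np.any(tree.flows <= 0):
        raise ValueError("flows must be computed and positive before setting radii")
    c = optimal_radius_coefficient(tree.eta, tree.m_b)
    tree.radii = c * np.cbrt(tree.flows)
    return tree


def tree_cost(tree: VascularTree, *, split: bool = False):
    """Total metabolic + viscous power of the tree in uW.

    f = sum_a (m_b pi r_a^2 + 8 eta_a Q_a^2 / (pi r_a^4)) l_a.

    With ``split=True`` returns ``(total, P_vol, P_vis)``.
    """
    l = tree.lengths
    p_vol = float(np.sum(tree.m_b * np.pi * tree.radii**2 * l))
    p_vis = float(
        np.sum(8.0 * tree.viscosities * tree.flows**2 / (np.pi * tree.radii**4) * l)
    )
    if split:
        return p_vol + p_vis, p_vol, p_vis
    return p_vol + p_vis


def node_pressures(tree: VascularTree) -> np.ndarray:
    """Pressure at every node from the root pressure and Poiseuille drops.

    For a supplying tree the pressure decreases from root to leaf; for a
    draining tree (stored with the same root->leaf flow convention, but
    physically flowing leaf->root) it increases from root to leaf.
    """
    sign = -1.0 if tree.role == "supplying" else 1.0
    dp = tree.pressure_drops
    p = np.empty(tree.n_nodes)
    p[tree.root] = tree.p_root
    for v in tree._topo_order[1:]:
        s = tree._seg_of_node[v]
        p[v] = p[tree.parent[v]] + sign * dp[s]
    return p


@dataclass
class VascularForest:
    """A collection of trees sharing one perfusion domain.

    ``pair_index`` lists each unordered tree pair once; intersection
    records are quadruples ``(seg_i, seg_j, c_i, c_j)`` per pair, filled
    by :func:`perfusim.synthesis.detect_intersections`.
    """

    trees: list
    clearance: float = 0.0
    intersections: dict = field(default_factory=dict)

    @property
    def pair_index(self):
        n = len(self.trees)
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
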