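"""Synthetic vascular tree generation.

The generator follows the constructive-optimization recipe common to
CCO-style methods: sample terminal sites uniformly in the perfusion
domain, connect them to the root through an initial binary topology,
explore alternative topologies with parent-swap moves under a simulated
annealing (SA) schedule, and finally relax the interior branching-node
positions to a local optimum of the total-power objective.

Radii never enter the search directly: at the power-optimal radius
r = (16 eta / (m_b pi^2))^(1/6) Q^(1/3) the per-segment power weight
collapses to w_opt(Q) = (3/2) m_b pi c^2 Q^(2/3), so the tree cost is
k * sum_a Q_a^(2/3) l_a and topology moves can be scored incrementally
along the two affected root paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import segment_segment_closest_points
from .tree import (
    VascularForest,
    VascularTree,
    compute_flows,
    optimal_radii,
    optimal_radius_coefficient,
)

__all__ = [
    "DomainSpec",
    "GenerationConfig",
    "sample_terminals",
    "initial_topology",
    "sa_accept",
    "optimize_topology",
    "relax_geometry",
    "generate_tree",
    "generate_forest",
    "detect_intersections",
]


@dataclass
class DomainSpec:
    """Perfusion domain with a deterministic point-membership test.

    kind "disk": ``params = {"center": (x, y), "radius": R}`` (2D).
    kind "rectangle": ``params = {"bounds": (xmin, xmax, ymin, ymax)}`` (2D)
    or with an extra ``(zmin, zmax)`` pair (3D box).
    kind "mesh-bounded": ``params = {"mesh": Mesh}`` - membership by
    point-in-triangulation.
    """

    kind: str
    params: dict
    dim: int = 2

    @classmethod
    def disk(cls, radius: float, center=(0.0, 0.0)) -> "DomainSpec":
        return cls("disk", {"center": tuple(center), "radius": float(radius)})

    @classmethod
    def rectangle(cls, bounds) -> "DomainSpec":
        b = np.asarray(bounds, float).ravel()
        return cls("rectangle", {"bounds": tuple(b)}, dim=len(b) // 2)

    def contains(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))[:, : self.dim]
        if self.kind == "disk":
            c = np.asarray(self.params["center"], float)
            return np.linalg.norm(pts - c, axis=1) <= self.params["radius"]
        if self.kind == "rectangle":
            b = np.asarray(self.params["bounds"], float).reshape(-1, 2)
            ok = np.ones(len(pts), dtype=bool)
            for k in range(self.dim):
                ok &= (pts[:, k] >= b[k, 0]) & (pts[:, k] <= b[k, 1])
            return ok
        if self.kind == "mesh-bounded":
            return self.params["mesh"].contains(pts)
        raise ValueError(f"unknown domain kind {self.kind!r}")

    def bounding_box(self) -> np.ndarray:
        if self.kind == "disk":
            c = np.asarray(self.params["center"], float)
            r = self.params["radius"]
            return np.array([[c[0] - r, c[0] + r], [c[1] - r, c[1] + r]])
        if self.kind == "rectangle":
            return np.asarray(self.params["bounds"], float).reshape(-1, 2)
        if self.kind == "mesh-bounded":
            return self.params["mesh"].bounding_box()
        raise ValueError(self.kind)

    def measure(self) -> float:
        """Area (2D) / volume (3D) of the domain."""
        if self.kind == "disk":
            return float(np.pi * self.params["radius"] ** 2)
        if self.kind == "rectangle":
            b = self.bounding_box()
            return float(np.prod(b[:, 1] - b[:, 0]))
        if self.kind == "mesh-bounded":
            return float(self.params["mesh"].total_volume())
        raise ValueError(self.kind)


@dataclass
class GenerationConfig:
    n_term: int = 500
    root_position: tuple = (0.0, 0.0)
    q_perf: float = 80.0
    p_root: float = 0.4
    m_b: float = 0.6
    eta: float = 3.6e-6
    role: str = "supplying"
    # simulated annealing schedule
    t0: Optional[float] = None       # None -> std of 100 random candidate swaps
    cooling: float = 0.9
    swaps_per_temperature: Optional[int] = None  # None -> n_term
    cooling_steps: int = 60
    # geometric relaxation
    l_min: float = 1e-3
    relax_sweeps: int = 200
    relax_tol: float = 1e-10
    clearance: float = 0.0
    seed: int = 0
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.l_min <= 0:
            raise ValueError("l_min must be positive")


def sample_terminals(domain: DomainSpec, n: int, seed) -> np.ndarray:
    """Uniform rejection sampling of ``n`` terminal sites inside the domain."""
    if n < 1:
        raise ValueError("need at least one terminal")
    box = domain.bounding_box()
    if np.any(box[:, 1] <= box[:, 0]):
        raise ValueError("degenerate domain bounding box")
    rng = np.random.default_rng(seed)
    out = np.empty((0, domain.dim))
    while len(out) < n:
        cand = rng.uniform(box[:, 0], box[:, 1], size=(max(2 * n, 64), domain.dim))
        out = np.vstack([out, cand[domain.contains(cand)]])
    return out[:n]


# ---------------------------------------------------------------------------
# initial topology


def initial_topology(terminals, root, *, q_perf=1.0, **tree_kwargs) -> VascularTree:
    """Binary tree connecting the root to all terminals.

    Small problems (<= 4000 terminals) use greedy centroid agglomeration;
    larger ones use recursive spatial bisection, which needs no pairwise
    distance matrix.  Flows and power-optimal radii are set on the result.
    """
    terminals = np.atleast_2d(np.asarray(terminals, float))
    root = np.asarray(root, float)
    n = len(terminals)
    dim = terminals.shape[1]
    if root.shape[0] != dim:
        raise ValueError("root/terminal dimension mismatch")

    # node layout: 0 = root, 1..n = terminals, n+1.. = internal
    if n == 1:
        pos = np.vstack([root, terminals])
        parent = np.array([-1, 0])
        tree = VascularTree(pos, parent, q_perf=q_perf, **tree_kwargs)
        return optimal_radii(compute_flows(tree))

    n_internal = n - 1
    pos = np.zeros((1 + n + n_internal, dim))
    pos[0] = root
    pos[1 : n + 1] = terminals
    parent = np.full(1 + n + n_internal, -1, dtype=np.int64)

    if n <= 4000:
        top = _greedy_agglomeration(terminals, pos, parent, n)
    else:
        top = _recursive_bisection(terminals, pos, parent, n)
    parent[top] = 0  # root segment
    tree = VascularTree(pos, parent, q_perf=q_perf, **tree_kwargs)
    return optimal_radii(compute_flows(tree))


def _greedy_agglomeration(terminals, pos, parent, n):
    """Repeatedly merge the globally closest active pair of clusters."""
    from scipy.cluster.hierarchy import linkage

    z = linkage(terminals, method="centroid")
    sizes = np.ones(n + n - 1)
    centroids = np.zeros((2 * n - 1, terminals.shape[1]))
    centroids[:n] = terminals
    # cluster id c (scipy) -> node index in the tree layout
    node_of = np.empty(2 * n - 1, dtype=np.int64)
    node_of[:n] = np.arange(1, n + 1)
    next_internal = n + 1
    for k, (a, b, _, _) in enumerate(z):
        a, b = int(a), int(b)
        cid = n + k
        sizes[cid] = sizes[a] + sizes[b]
        centroids[cid] = (
            sizes[a] * centroids[a] + sizes[b] * centroids[b]
        ) / sizes[cid]
        node_of[cid] = next_internal
        pos[next_internal] = centroids[cid]
        parent[node_of[a]] = next_internal
        parent[node_of[b]] = next_internal
        next_internal += 1
    return next_internal - 1  # top cluster node


def _recursive_bisection(terminals, pos, parent, n):
    """Split along the axis of largest spread; O(n log n), no n^2 matrix."""
    next_internal = [n + 1]

    stack = [(np.arange(n), None)]
    built = {}
    # iterative post-order: first pass pushes children, second pass links
    order = []
    while stack:
        idx, tag = stack.pop()
        order.append((idx, tag))
        if len(idx) > 1:
            t = terminals[idx]
            ax = int(np.argmax(t.max(axis=0) - t.min(axis=0)))
            key = np.argsort(t[:, ax], kind="stable")
            half = len(idx) // 2
            stack.append((idx[key[:half]], (id(idx), 0)))
            stack.append((idx[key[half:]], (id(idx), 1)))
    # process in reverse so children exist before parents
    for idx, tag in reversed(order):
        if len(idx) == 1:
            built[idx.tobytes()] = int(idx[0]) + 1
        else:
            t = terminals[idx]
            ax = int(np.argmax(t.max(axis=0) - t.min(axis=0)))
            key = np.argsort(t[:, ax], kind="stable")
            half = len(idx) // 2
            left = built[idx[key[:half]].tobytes()]
            right = built[idx[key[half:]].tobytes()]
            node = next_internal[0]
            next_internal[0] += 1
            pos[node] = t.mean(axis=0)
            parent[left] = node
            parent[right] = node
            built[idx.tobytes()] = node
    return built[np.arange(n).tobytes()]


# ---------------------------------------------------------------------------
# simulated annealing topology search


def sa_accept(df: float, temperature: float, rng) -> bool:
    """Metropolis acceptance: improving moves always, others with exp(-df/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if df <= 0:
        return True
    return bool(rng.random() < np.exp(-df / temperature))


class _SwapState:
    """Incremental cost bookkeeping for parent-swap moves.

    cost = k * sum_v leaf(v)^(2/3) * |x_v - x_parent(v)|  over non-root v,
    with k = 1.5 m_b pi c^2 Q_term^(2/3) (power at the optimal radius).
    """

    def __init__(self, tree: VascularTree):
        self.pos = tree.positions
        self.parent = tree.parent.copy()
        self.root = tree.root
        n = tree.n_nodes
        self.leaf = np.zeros(n)
        self.leaf[tree.leaves] = 1.0
        for v in tree._topo_order[::-1]:
            p = self.parent[v]
            if p >= 0:
                self.leaf[p] += self.leaf[v]
        c = optimal_radius_coefficient(tree.eta, tree.m_b)
        self.k = 1.5 * tree.m_b * np.pi * c * c * tree.q_term ** (2.0 / 3.0)
        self.is_leaf = np.zeros(n, dtype=bool)
        self.is_leaf[tree.leaves] = True

    def seg_cost(self, v, leaf_v=None) -> float:
        lv = self.leaf[v] if leaf_v is None else leaf_v
        return self.k * lv ** (2.0 / 3.0) * np.linalg.norm(
            self.pos[v] - self.pos[self.parent[v]]
        )

    def total_cost(self) -> float:
        mask = self.parent >= 0
        v = np.flatnonzero(mask)
        l = np.linalg.norm(self.pos[v] - self.pos[self.parent[v]], axis=1)
        return float(self.k * np.sum(self.leaf[v] ** (2.0 / 3.0) * l))

    def _path_to_root(self, v) -> list:
        path = []
        while v >= 0:
            path.append(v)
            v = self.parent[v]
        return path

    def is_ancestor(self, a, v) -> bool:
        while v >= 0:
            if v == a:
                return True
            v = self.parent[v]
        return False

    def propose(self, u, v):
        """Cost change of exchanging the parents of u and v, or None if invalid."""
        if u == v or u == self.root or v == self.root:
            return None
        if self.is_ancestor(u, v) or self.is_ancestor(v, u):
            return None
        pu, pv = self.parent[u], self.parent[v]
        if pu == pv:
            return None  # sibling swap is a no-op
        delta = self.leaf[v] - self.leaf[u]
        pa = self._path_to_root(pu)
        pb = self._path_to_root(pv)
        common = set(pa) & set(pb)
        df = 0.0
        # reattachment length changes (flows of u, v unchanged)
        df += self.k * self.leaf[u] ** (2 / 3) * (
            np.linalg.norm(self.pos[u] - self.pos[pv])
            - np.linalg.norm(self.pos[u] - self.pos[pu])
        )
        df += self.k * self.leaf[v] ** (2 / 3) * (
            np.linalg.norm(self.pos[v] - self.pos[pu])
            - np.linalg.norm(self.pos[v] - self.pos[pv])
        )
        # flow changes along the two disjoint ancestor paths
        for w in pa:
            if w in common or w == self.root:
                continue
            df += self.seg_cost(w, self.leaf[w] + delta) - self.seg_cost(w)
        for w in pb:
            if w in common or w == self.root:
                continue
            df += self.seg_cost(w, self.leaf[w] - delta) - self.seg_cost(w)
        return df, (u, v, pu, pv, delta, pa, pb, common)

    def apply(self, move):
        u, v, pu, pv, delta, pa, pb, common = move
        self.parent[u] = pv
        self.parent[v] = pu
        for w in pa:
            if w not in common:
                self.leaf[w] += delta
        for w in pb:
            if w not in common:
                self.leaf[w] -= delta


def optimize_topology(tree: VascularTree, config: GenerationConfig) -> VascularTree:
    """Simulated-annealing parent-swap search; returns the best tree seen.

    The temperature is multiplied by ``config.cooling`` after each batch of
    ``swaps_per_temperature`` proposals; ``t0=None`` initializes it with the
    median cost decrease over improving candidate swaps, which keeps the
    schedule scale-free while starting cold enough to descend (the raw
    spread of candidate moves is dominated by strongly uphill proposals).
    A greedy descent phase runs after the schedule until a full batch
    yields no improving move.
    """
    rng = np.random.default_rng(config.seed + 1)
    state = _SwapState(tree)
    n = tree.n_nodes
    cost = state.total_cost()
    best_cost = cost
    best_parent = state.parent.copy()

    swaps = config.swaps_per_temperature or max(tree.n_term, 1)
    steps = config.cooling_steps

    if steps <= 0 or swaps <= 0:
        return tree

    # locality-biased proposals: parent swaps between spatially close
    # nodes are far more likely to improve the cost than uniform pairs
    k_nbr = min(12, n - 1)
    _, nbrs = cKDTree(tree.positions[:, :2]).query(
        tree.positions[:, :2], k=k_nbr + 1
    )
    nbrs = np.atleast_2d(nbrs)[:, 1:]

    def _propose_pair():
        u = int(rng.integers(1, n))
        if k_nbr > 0 and rng.random() < 0.8:
            v = int(nbrs[u, rng.integers(k_nbr)])
        else:
            v = int(rng.integers(1, n))
        return u, v

    t = config.t0
    if t is None:
        # calibrate on the scale of *improving* candidate moves: the raw
        # spread of cost changes is dominated by large uphill proposals
        # and would keep the walk in the hot random regime throughout
        dfs = []
        tries = 0
        while len(dfs) < 200 and tries < 4000:
            tries += 1
            prop = state.propose(*_propose_pair())
            if prop is not None:
                dfs.append(prop[0])
        dfs = np.asarray(dfs)
        downhill = np.abs(dfs[dfs < 0])
        if downhill.size:
            t = float(np.median(downhill))
        elif dfs.size:
            t = float(np.quantile(np.abs(dfs), 0.05))
        else:
            t = 1.0
        t = t if t > 0 else 1.0

    for _ in range(steps):
        for _ in range(swaps):
            prop = state.propose(*_propose_pair())
            if prop is None:
                continue
            df, move = prop
            if sa_accept(df, t, rng):
                state.apply(move)
                cost += df
                if cost < best_cost:
                    best_cost = cost
                    best_parent = state.parent.copy()
        t *= config.cooling

    # final greedy descent: accept only improving swaps until a full
    # batch passes without one (bounded by the annealing budget)
    for _ in range(steps):
        improved = False
        for _ in range(swaps):
            prop = state.propose(*_propose_pair())
            if prop is None:
                continue
            df, move = prop
            if df < 0:
                state.apply(move)
                cost += df
                improved = True
                if cost < best_cost:
                    best_cost = cost
                    best_parent = state.parent.copy()
        if not improved:
            break

    out = VascularTree(
        tree.positions.copy(),
        best_parent,
        q_perf=tree.q_perf,
        p_root=tree.p_root,
        m_b=tree.m_b,
        eta=tree.eta,
        role=tree.role,
    )
    return optimal_radii(compute_flows(out))


# ---------------------------------------------------------------------------
# geometric relaxation


def relax_geometry(tree: VascularTree, config: GenerationConfig) -> VascularTree:
    """Relax interior branching-node positions to minimize sum_a w_a l_a.

    Root and terminal positions stay fixed; the power weights w_a are
    evaluated once at the current radii, so each interior node solves a
    weighted geometric-median (Fermat) problem over its graph neighbors.
    Uses blockwise Weiszfeld updates (monotone non-increasing objective);
    a node update that would shorten any incident segment below
    ``config.l_min`` is reverted.
    """
    tree = tree.copy()
    w = (
        tree.m_b * np.pi * tree.radii**2
        + 8.0 * tree.viscosities * tree.flows**2 / (np.pi * tree.radii**4)
    )
    # per-node incident (neighbor, weight) lists
    fixed = np.zeros(tree.n_nodes, dtype=bool)
    fixed[tree.root] = True
    fixed[tree.leaves] = True
    neighbors: list[list] = [[] for _ in range(tree.n_nodes)]
    for s, v in enumerate(tree.distal):
        u = tree.parent[v]
        neighbors[u].append((v, w[s]))
        neighbors[v].append((u, w[s]))

    pos = tree.positions

    def objective():
        return float(np.sum(w * tree.lengths))

    obj = objective()
    movable = [u for u in range(tree.n_nodes) if not fixed[u] and neighbors[u]]
    converged = False
    for _ in range(config.relax_sweeps):
        for u in movable:
            nbr = neighbors[u]
            num = np.zeros(3)
            den = 0.0
            old = pos[u].copy()
            ok = True
            for j, wj in nbr:
                d = np.linalg.norm(pos[u] - pos[j])
                d = max(d, config.l_min)
                num += wj * pos[j] / d
                den += wj / d
            if den <= 0:
                continue
            pos[u] = num / den
            for j, _ in nbr:
                if np.linalg.norm(pos[u] - pos[j]) < config.l_min:
                    ok = False
                    break
            if not ok:
                pos[u] = old
        new_obj = objective()
        if new_obj > obj + 1e-12 * max(abs(obj), 1.0):  # safety, shouldn't happen
            break
        if obj - new_obj <= config.relax_tol * max(abs(obj), 1.0):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged and config.relax_sweeps > 0:
        warnings.warn(
            f"geometry relaxation stopped after {config.relax_sweeps} sweeps "
            f"(objective {obj:.6g})",
            RuntimeWarning,
        )
    return tree


# ---------------------------------------------------------------------------
# full pipeline


def generate_tree(domain: DomainSpec, config: GenerationConfig) -> VascularTree:
    """Sample terminals, build, anneal and relax one tree."""
    terminals = sample_terminals(domain, config.n_term, config.seed)
    tree = initial_topology(
        terminals,
        np.asarray(config.root_position, float),
        q_perf=config.q_perf,
        p_root=config.p_root,
        m_b=config.m_b,
        eta=config.eta,
        role=config.role,
    )
    config.log["initial_cost"] = tree_cost_fast(tree)
    tree = optimize_topology(tree, config)
    config.log["annealed_cost"] = tree_cost_fast(tree)
    tree = relax_geometry(tree, config)
    tree = optimal_radii(compute_flows(tree))
    config.log["relaxed_cost"] = tree_cost_fast(tree)
    config.log["seed"] = config.seed
    return tree


def tree_cost_fast(tree: VascularTree) -> float:
    from .tree import tree_cost

    return tree_cost(tree)


def generate_forest(domain: DomainSpec, configs: list) -> VascularForest:
    """Generate one tree per config (distinct derived seeds) in a shared domain."""
    trees = []
    for k, cfg in enumerate(configs):
        trees.append(generate_tree(domain, cfg))
    clearance = max((c.clearance for c in configs), default=0.0)
    return VascularForest(trees=trees, clearance=clearance)


def detect_intersections(forest: VascularForest) -> dict:
    """Pairwise cross-tree segment intersection records.

    For each unordered tree pair computes the closest points (c_i, c_j)
    between every candidate cross-tree segment pair (KD-tree pruned) and
    records ``(seg_i, seg_j, c_i, c_j, dist)`` whenever
    ||c_i - c_j|| < r_i + r_j.  Exact for parallel and degenerate
    segments.
    """
    if len(forest.trees) < 2:
        raise ValueError("intersection detection requires at least two trees")
    records = {}
    for (i, j) in forest.pair_index:
        ti, tj = forest.trees[i], forest.trees[j]
        p1 = ti.positions[ti.proximal]
        q1 = ti.positions[ti.distal]
        p2 = tj.positions[tj.proximal]
        q2 = tj.positions[tj.distal]
        mid_i = 0.5 * (p1 + q1)
        mid_j = 0.5 * (p2 + q2)
        half_i = 0.5 * np.linalg.norm(q1 - p1, axis=1)
        half_j = 0.5 * np.linalg.norm(q2 - p2, axis=1)
        reach = (
            half_i.max(initial=0.0)
            + half_j.max(initial=0.0)
            + ti.radii.max(initial=0.0)
            + tj.radii.max(initial=0.0)
        )
        kd = cKDTree(mid_j)
        cand = kd.query_ball_point(mid_i, r=reach)
        ii, jj = [], []
        for a, lst in enumerate(cand):
            ii.extend([a] * len(lst))
            jj.extend(lst)
        if not ii:
            records[(i, j)] = []
            continue
        ii = np.asarray(ii)
        jj = np.asarray(jj)
        c1, c2, dist = segment_segment_closest_points(p1[ii], q1[ii], p2[jj], q2[jj])
        hit = dist < ti.radii[ii] + tj.radii[jj]
        records[(i, j)] = [
            (int(a), int(b), ca.copy(), cb.copy(), float(d))
            for a, b, ca, cb, d in zip(ii[hit], jj[hit], c1[hit], c2[hit], dist[hit])
        ]
    forest.intersections = records
    return records
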