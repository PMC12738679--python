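import numpy as np
import pytest

from perfusim import (
    DomainSpec,
    GenerationConfig,
    VascularForest,
    VascularTree,
    compute_flows,
    detect_intersections,
    initial_topology,
    optimal_radii,
    optimize_topology,
    relax_geometry,
    sa_accept,
    sample_terminals,
    tree_cost,
)


def test_sample_terminals_inside_and_deterministic():
    dom = DomainSpec.disk(radius=3.0, center=(1.0, -1.0))
    a = sample_terminals(dom, 500, seed=7)
    b = sample_terminals(dom, 500, seed=7)
    assert np.array_equal(a, b)
    assert dom.contains(a).all()
    # mean radial distance of uniform disk samples ~ 2R/3
    r = np.linalg.norm(a - np.array([1.0, -1.0]), axis=1)
    assert r.mean() == pytest.approx(2.0, abs=0.1)


def test_initial_topology_node_count_small_and_large():
    rng = np.random.default_rng(0)
    for n in (1, 2, 10, 300):
        terms = rng.random((n, 2))
        tree = initial_topology(terms, np.array([0.5, -0.5]))
        assert tree.n_term == n
        assert tree.n_segments == max(2 * n - 1, 1)
        res = tree.kirchhoff_residuals()
        assert res.size == 0 or np.abs(res).max() < 1e-12


def test_initial_topology_bisection_path():
    rng = np.random.default_rng(1)
    terms = rng.random((4500, 2))  # above the agglomeration cutoff
    tree = initial_topology(terms, np.array([0.5, 0.5]))
    assert tree.n_segments == 2 * 4500 - 1
    assert tree.n_term == 4500


def test_sa_accept_improving_always_and_rate():
    rng = np.random.default_rng(3)
    assert sa_accept(-1.0, 0.5, rng)
    assert sa_accept(0.0, 0.5, rng)
    # at df == T the acceptance probability is exp(-1)
    hits = sum(sa_accept(1.0, 1.0, rng) for _ in range(20000)) / 20000
    assert hits == pytest.approx(np.exp(-1), abs=0.015)
    with pytest.raises(ValueError):
        sa_accept(1.0, 0.0, rng)


def test_optimize_topology_never_worse():
    rng = np.random.default_rng(5)
    terms = rng.random((60, 2)) * 4
    tree = initial_topology(terms, np.array([2.0, -0.5]), q_perf=10.0)
    cfg = GenerationConfig(n_term=60, cooling_steps=20, seed=9)
    out = optimize_topology(tree, cfg)
    assert out.n_term == tree.n_term
    assert out.n_segments == tree.n_segments
    assert tree_cost(out) <= tree_cost(tree) * (1 + 1e-12)
    assert np.abs(out.kirchhoff_residuals()).max() < 1e-12


def test_relax_geometry_decreases_cost_keeps_endpoints():
    rng = np.random.default_rng(6)
    terms = rng.random((40, 2)) * 4
    root = np.array([2.0, -0.5])
    tree = initial_topology(terms, root, q_perf=10.0)
    cfg = GenerationConfig(n_term=40, relax_sweeps=80, relax_tol=1e-9)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        relaxed = relax_geometry(tree, cfg)
    w = tree.m_b * np.pi * tree.radii**2 + 8 * tree.viscosities * tree.flows**2 / (
        np.pi * tree.radii**4
    )
    assert np.sum(w * relaxed.lengths) <= np.sum(w * tree.lengths) + 1e-12
    # root and terminals pinned
    assert np.allclose(relaxed.positions[tree.root], tree.positions[tree.root])
    assert np.allclose(relaxed.positions[tree.leaves], tree.positions[tree.leaves])
    # relaxation never shortens a segment below l_min (pre-existing
    # shorter segments from the initial topology may persist)
    floor = min(tree.lengths.min(), cfg.l_min)
    assert relaxed.lengths.min() >= floor * (1 - 1e-9)


def test_relaxed_interior_node_is_weighted_fermat_point():
    """Single interior node: relaxation must find the weighted geometric median."""
    pos = np.array([[0.0, 0.0], [0.3, 0.8], [2.0, 1.0], [2.0, -1.0]])
    tree = VascularTree(pos, [-1, 0, 1, 1], q_perf=2.0)
    optimal_radii(compute_flows(tree))
    cfg = GenerationConfig(n_term=2, relax_sweeps=500, relax_tol=1e-14)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        relaxed = relax_geometry(tree, cfg)
    w = tree.m_b * np.pi * tree.radii**2 + 8 * tree.viscosities * tree.flows**2 / (
        np.pi * tree.radii**4
    )
    anchors = pos[[0, 2, 3]]
    weights = w[[tree.segment_of_node(1), tree.segment_of_node(2), tree.segment_of_node(3)]]

    def objective(p):
        return np.sum(weights * np.linalg.norm(anchors - p, axis=1))

    # brute-force grid oracle around the relaxed point
    best = relaxed.positions[1, :2]
    grid = np.linspace(-0.05, 0.05, 21)
    vals = [objective(best + np.array([dx, dy])) for dx in grid for dy in grid]
    assert objective(best) <= min(vals) + 1e-6


def test_detect_intersections_on_crossing_trees():
    # two 2-node trees whose segments cross at the origin
    t1 = VascularTree(np.array([[-1.0, 0.0], [1.0, 0.0]]), [-1, 0], q_perf=1.0)
    t2 = VascularTree(np.array([[0.0, -1.0], [0.0, 1.0]]), [-1, 0], q_perf=1.0)
    for t in (t1, t2):
        optimal_radii(compute_flows(t))
    forest = VascularForest(trees=[t1, t2])
    rec = detect_intersections(forest)
    assert len(rec[(0, 1)]) == 1
    _, _, c1, c2, d = rec[(0, 1)][0]
    assert d == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(c1[:2], [0, 0], atol=1e-12)

    # separated trees: no intersections
    t3 = VascularTree(np.array([[10.0, 10.0], [11.0, 10.0]]), [-1, 0], q_perf=1.0)
    optimal_radii(compute_flows(t3))
    rec2 = detect_intersections(VascularForest(trees=[t1, t3]))
    assert rec2[(0, 1)] == []
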