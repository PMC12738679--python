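import numpy as np
import pytest

from perfusim import (
    HomogenizationConfig,
    RveSpec,
    SourceField,
    VascularTree,
    clip_segment_to_rve,
    compartment_average_pressure,
    compartmentalize,
    compute_flows,
    homogenize_field,
    micro_permeability,
    optimal_radii,
    perfusion_coefficient,
    permeability_tensor,
    rectangle_mesh,
    segment_average_pressure,
)


def test_rve_spec_volumes_and_validation():
    rve = RveSpec(center=[0.0, 0.0], radius=2.0)
    assert rve.nominal_volume == pytest.approx(4 * np.pi)
    assert rve.effective_volume == pytest.approx(4 * np.pi)
    with pytest.raises(ValueError):
        RveSpec(center=[0, 0], radius=-1.0)
    with pytest.raises(ValueError):
        RveSpec(center=[0, 0], radius=1.0, effective_volume=2 * np.pi + 1)


def test_clip_segment_to_rve_chord():
    rve = RveSpec(center=[0.0, 0.0], radius=1.0)
    cs = clip_segment_to_rve([-2.0, 0.0], [2.0, 0.0], rve, segment_id=7)
    assert cs is not None and cs.segment == 7
    assert cs.s1 == pytest.approx(0.25) and cs.s2 == pytest.approx(0.75)
    assert cs.length == pytest.approx(2.0)
    assert np.allclose(np.abs(cs.orientation), [1.0, 0.0])
    assert cs.s_mid == pytest.approx(0.5)
    assert clip_segment_to_rve([5.0, 5.0], [6.0, 5.0], rve) is None


def test_permeability_single_segment_closed_form():
    # r = 0.01 mm, dl = 0.01 mm, eta = 1e-6, |V| = 1 mm^2, x-oriented
    K = permeability_tensor([0.01], [0.01], [1e-6], [[1.0, 0.0]], 1.0)
    assert K[0, 0] == pytest.approx(np.pi / 8 * 1e-4, rel=1e-12)
    assert K[0, 0] == pytest.approx(3.926990816987e-5, rel=1e-9)
    assert K[1, 1] == 0.0 and K[0, 1] == 0.0


def test_permeability_trace_identity_and_psd():
    rng = np.random.default_rng(12)
    n = 500
    r = rng.uniform(0.005, 0.05, n)
    dl = rng.uniform(0.01, 0.3, n)
    eta = rng.uniform(1e-6, 5e-6, n)
    phi = rng.uniform(0, np.pi, n)
    e = np.column_stack([np.cos(phi), np.sin(phi)])
    vol = 2.3
    K = permeability_tensor(r, dl, eta, e, vol)
    # trace = pi/(8|V|) sum r^4 dl / eta, independent of orientations
    assert np.trace(K) == pytest.approx(
        np.pi / (8 * vol) * np.sum(r**4 * dl / eta), rel=1e-12
    )
    assert np.allclose(K, K.T)
    assert np.linalg.eigvalsh(K).min() >= -1e-16


def test_permeability_rotation_equivariance():
    rng = np.random.default_rng(3)
    n = 64
    r = rng.uniform(0.01, 0.03, n)
    dl = rng.uniform(0.1, 0.4, n)
    phi = rng.uniform(0, np.pi, n)
    e = np.column_stack([np.cos(phi), np.sin(phi)])
    a = 0.7
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    K = permeability_tensor(r, dl, 1e-6, e, 1.0)
    K_rot = permeability_tensor(r, dl, 1e-6, e @ R.T, 1.0)
    assert np.allclose(K_rot, R @ K @ R.T, atol=1e-18)


def test_permeability_empty_and_bad_volume():
    assert np.allclose(permeability_tensor([], [], [], np.empty((0, 2)), 1.0), 0.0)
    with pytest.raises(ValueError):
        permeability_tensor([0.01], [0.01], [1e-6], [[1, 0]], 0.0)


def test_segment_average_pressure_examples():
    # full segment: plain midpoint average
    assert segment_average_pressure(0.0, 1.0, 2.0, 4.0) == pytest.approx(3.0)
    # clipped [0.25, 0.75] of a linear drop is still the midpoint value
    assert segment_average_pressure(0.25, 0.75, 2.0, 4.0) == pytest.approx(3.0)
    # clipped near the distal end
    assert segment_average_pressure(0.5, 1.0, 2.0, 4.0) == pytest.approx(3.5)


def test_compartment_average_pressure_weighting():
    # two segments, equal length; volume weight ~ r^2
    p = compartment_average_pressure([0.02, 0.01], [1.0, 1.0], [1.0, 2.0])
    w = np.array([4.0, 1.0])
    assert p == pytest.approx((w * [1.0, 2.0]).sum() / w.sum())
    assert compartment_average_pressure([], [], []) is None


def test_perfusion_coefficient_examples():
    assert perfusion_coefficient(1.0, 3.0, 1.0) == pytest.approx(0.5)
    assert perfusion_coefficient(1.0, 1.0, 3.0) == pytest.approx(0.5)  # sign-free
    assert perfusion_coefficient(1.0, 2.0, 2.0) == 0.0  # zero gap
    assert perfusion_coefficient(0.0, 3.0, 1.0) == 0.0
    assert perfusion_coefficient(1.0, None, 1.0) == 0.0  # empty compartment


def test_micro_permeability():
    # liver-scale constants: k = 2e-8 mm^2, eta = 3.6e-6 kPa s
    assert micro_permeability(3.6e-6, k_micro=2e-8) == pytest.approx(1.0 / 180.0)
    # Kozeny-Carman: d = 1, phi = 0.5 -> k = 0.5^3 / (1 - 0.25) = 1/6
    assert micro_permeability(1.0, d_char=1.0, phi_micro=0.5) == pytest.approx(1 / 6)
    with pytest.raises(ValueError):
        micro_permeability(1.0)
    with pytest.raises(ValueError):
        micro_permeability(1.0, d_char=1.0, phi_micro=1.5)


def test_source_field_peak_linearity_mass():
    sigma = 0.3
    f = SourceField([[0.0, 0.0]], [2.0], sigma)
    # peak value Q / (2 pi sigma^2)
    assert f([[0.0, 0.0]])[0] == pytest.approx(2.0 / (2 * np.pi * sigma**2))
    # linear in the flows
    g = SourceField([[0.0, 0.0]], [4.0], sigma)
    x = np.random.default_rng(0).uniform(-1, 1, (50, 2))
    assert np.allclose(g(x), 2 * f(x))
    assert f.total_flow == pytest.approx(2.0)
    # >= 99 % of the mass within a disk of radius 5 sigma (midpoint rule)
    h = 0.02
    grid = np.arange(-5 * sigma, 5 * sigma, h) + h / 2
    X, Y = np.meshgrid(grid, grid)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    inside = np.linalg.norm(pts, axis=1) <= 5 * sigma
    mass = f(pts[inside]).sum() * h * h
    assert mass >= 0.99 * f.total_flow
    with pytest.raises(ValueError):
        SourceField([[0.0, 0.0]], [1.0], 0.0)


def _y_tree():
    """Root chain into two leaves spanning two radius classes."""
    pos = np.array(
        [[-0.9, 0.0], [-0.2, 0.0], [0.35, 0.45], [0.35, -0.45]]
    )
    tree = VascularTree(pos, [-1, 0, 1, 1], q_perf=2.0, p_root=0.4)
    optimal_radii(compute_flows(tree))
    return tree


def test_homogenize_field_shapes_empties_and_floor():
    tree = _y_tree()
    r_split = float(tree.radii.max()) * 0.999  # root resolved, rest homogenized
    scheme = compartmentalize(tree, [r_split, 0.0])
    mesh = rectangle_mesh((-1.0, 1.0, -1.0, 1.0), 4, 4)
    cfg = HomogenizationConfig(rve_radius=0.35, sigma=0.3, p_ref_micro=0.0)
    perm, coupling, sources = homogenize_field([scheme], mesh, cfg)
    K = perm[0][1]
    assert K.K.shape == (mesh.n_cells, 2, 2)
    assert K.floored.shape == (mesh.n_cells,)
    # far-away cells hold no vessels: flagged and floored isotropically
    cent = mesh.centroids()
    far = np.linalg.norm(cent - [-0.9, 0.9], axis=1) < 0.2
    assert K.floored[far].all()
    assert np.allclose(K.K[far][:, 0, 0], K.floor_value)
    # cells whose RVE covers the bifurcation see both branch orientations:
    # full-rank tensors, not floored
    near = np.linalg.norm(cent - [-0.25, 0.25], axis=1) < 0.15
    assert near.any() and not K.floored[near].any()
    # cells seeing a single straight vessel are rank-deficient: flagged,
    # but the isotropic floor is negligible against the vessel contribution
    single = np.linalg.norm(cent - [0.25, 0.25], axis=1) < 0.15
    assert K.floored[single].all()
    assert np.trace(K.K[single].sum(axis=0)) > 1e3 * K.floor_value
    # terminal coupling is nonnegative and supported near the leaves only
    assert (coupling[0].beta_terminal >= 0).all()
    assert coupling[0].beta_terminal.max() > 0
    # supplying tree gets a Gaussian source carrying the full perfusion flow
    assert sources[0] is not None
    assert sources[0].total_flow == pytest.approx(2.0)


def test_homogenize_field_beta_zero_where_empty():
    tree = _y_tree()
    r_split = float(tree.radii.max()) * 0.999
    scheme = compartmentalize(tree, [r_split, 0.0])
    mesh = rectangle_mesh((-1.0, 1.0, -1.0, 1.0), 4, 4)
    cfg = HomogenizationConfig(rve_radius=0.25, sigma=0.3, p_ref_micro=0.0)
    perm, coupling, _ = homogenize_field([scheme], mesh, cfg)
    empty = ~np.isfinite(coupling[0].p_out_terminal)
    assert np.all(coupling[0].beta_terminal[empty] == 0.0)
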