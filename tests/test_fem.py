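import numpy as np
import pytest

from perfusim import (
    CompartmentModel,
    MultiCompartmentProblem,
    assemble,
    conservation_check,
    postprocess,
    rectangle_mesh,
    solve,
)
from perfusim.fem import FeSpace, _triangle_quadrature


def _identity_K(mesh, scale=1.0):
    return np.broadcast_to(scale * np.eye(2), (mesh.n_cells, 2, 2)).copy()


def test_quadrature_exactness():
    # order-p rule integrates monomials xi^a eta^b, a+b <= p, exactly
    from math import factorial

    for order in (2, 4, 6):
        xi, w = _triangle_quadrature(order)
        assert w.sum() == pytest.approx(0.5, rel=1e-13)
        for a in range(order + 1):
            for b in range(order + 1 - a):
                exact = (
                    factorial(a) * factorial(b) / factorial(a + b + 2)
                )  # int over unit triangle
                got = np.sum(w * xi[:, 0] ** a * xi[:, 1] ** b)
                assert got == pytest.approx(exact, rel=1e-11)


def test_fespace_partition_of_unity_and_area():
    mesh = rectangle_mesh((0.0, 2.0, 0.0, 1.0), 5, 3)
    for degree in (1, 2):
        space = FeSpace(mesh, degree)
        ones = np.ones(space.n_dofs)
        assert space.integrate(ones) == pytest.approx(2.0, rel=1e-12)
        # load vector sums to the domain measure
        assert space.load_vector().sum() == pytest.approx(2.0, rel=1e-12)
        # interpolation of a degree-`degree` polynomial is exact
        x = space.dof_coords
        p = x[:, 0] ** degree + 0.5 * x[:, 1]
        xi = np.array([[0.25, 0.4], [0.1, 0.1]])
        vals = space.evaluate(p, xi)
        xq = space.physical_points(xi)
        assert np.allclose(vals, xq[..., 0] ** degree + 0.5 * xq[..., 1], atol=1e-12)


def test_matrix_symmetry_and_constant_nullspace(unit_square_mesh):
    mesh = unit_square_mesh
    n = mesh.n_cells
    comps = [
        CompartmentModel("a", _identity_K(mesh), source=np.ones(n)),
        CompartmentModel("b", _identity_K(mesh, 2.0)),
    ]
    prob = MultiCompartmentProblem(mesh, comps, couplings={(0, 1): np.full(n, 3.0)})
    sys_ = assemble(prob, gauge="zero-mean")
    A = sys_.A_sym
    assert abs(A - A.T).max() < 1e-12
    # constants (equal in both compartments) lie in the nullspace
    one = np.ones(A.shape[0])
    assert np.abs(A @ one).max() < 1e-10


def test_gauge_fail_raises_without_sink(unit_square_mesh):
    mesh = unit_square_mesh
    comps = [CompartmentModel("a", _identity_K(mesh))]
    prob = MultiCompartmentProblem(mesh, comps)
    with pytest.raises(ValueError):
        assemble(prob, gauge="fail")
    with pytest.raises(ValueError):
        assemble(prob, gauge="bogus")


def test_sink_anchors_coupled_component(unit_square_mesh):
    mesh = unit_square_mesh
    n = mesh.n_cells
    comps = [
        CompartmentModel("a", _identity_K(mesh), source=np.full(n, 2.0)),
        CompartmentModel(
            "b",
            _identity_K(mesh),
            sink_beta=np.full(n, 0.5),
            sink_pressure=np.zeros(n),
        ),
    ]
    prob = MultiCompartmentProblem(mesh, comps, couplings={(0, 1): np.full(n, 0.5)})
    sys_ = assemble(prob, gauge="fail")  # must not raise: sink anchors both
    assert sys_.anchored.all()
    sol = solve(sys_)
    chk = conservation_check(sol)
    assert abs(chk["mass_residual"]) < 1e-10 * max(chk["total_source"], 1.0)
    assert chk["energy"] >= 0.0
    # uniform equilibrium: p constant per compartment,
    # gap p_a - p_b = theta/beta = 4, p_b = theta/beta_sink = 4
    pa = sol.pressure_cells(0)
    pb = sol.pressure_cells(1)
    assert np.allclose(pa - pb, 4.0, atol=1e-9)
    assert np.allclose(pb, 4.0, atol=1e-9)
    # exchange rate is beta * gap and antisymmetric
    q = sol.exchange_rate(0, 1)
    assert np.allclose(q, 0.5 * 4.0, atol=1e-9)
    assert np.allclose(sol.exchange_rate(1, 0), -q)
    out = postprocess(sol)
    assert "a->b" in out["exchange"]
    assert np.allclose(out["velocity"]["a"], 0.0, atol=1e-8)


def test_negative_coupling_rejected(unit_square_mesh):
    mesh = unit_square_mesh
    comps = [
        CompartmentModel("a", _identity_K(mesh)),
        CompartmentModel("b", _identity_K(mesh)),
    ]
    with pytest.raises(ValueError):
        MultiCompartmentProblem(
            mesh, comps, couplings={(0, 1): np.full(mesh.n_cells, -1.0)}
        )


def _mms_error(nx, degree):
    """Relative L2 error for p* = cos(pi x) cos(pi y), K = I, pure Neumann."""
    mesh = rectangle_mesh((0.0, 1.0, 0.0, 1.0), nx, nx)

    def theta(x):
        return 2 * np.pi**2 * np.cos(np.pi * x[:, 0]) * np.cos(np.pi * x[:, 1])

    comps = [CompartmentModel("p", _identity_K(mesh), source=theta)]
    prob = MultiCompartmentProblem(mesh, comps, degree=degree)
    sol = solve(assemble(prob, gauge="zero-mean"))
    space = sol.space
    xi, w = _triangle_quadrature(6)
    ph = space.evaluate(sol.pressures[0], xi)
    xq = space.physical_points(xi)
    pex = np.cos(np.pi * xq[..., 0]) * np.cos(np.pi * xq[..., 1])
    # remove the (arbitrary) gauge shift before comparing
    shift = np.einsum("cq,q,c->", ph - pex, w, space.detB)  # integral of error
    err = ph - pex - shift / space.mesh.total_volume()
    e2 = np.einsum("cq,q,c->", err**2, w, space.detB)
    n2 = np.einsum("cq,q,c->", pex**2, w, space.detB)
    return np.sqrt(e2 / n2)


@pytest.mark.parametrize("degree,min_rate", [(1, 1.8), (2, 2.7)])
def test_mms_convergence(degree, min_rate):
    e_coarse = _mms_error(8, degree)
    e_fine = _mms_error(16, degree)
    rate = np.log2(e_coarse / e_fine)
    assert rate > min_rate
    assert e_fine < e_coarse
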