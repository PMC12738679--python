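import numpy as np
import pytest

from perfusim import (
    RvePopulationSpec,
    SpectralPermeability,
    analytical_update,
    beta_update,
    deformation_mode,
    generate_rve_population,
    lagrangian_transform,
    porosity_ratio,
    pull_back_permeability,
    push_forward_permeability,
    rehomogenize,
    segment_stretches,
    spectral_update,
    vessel_radius_update,
)


def _rot(a):
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def test_deformation_mode_trivials():
    R = deformation_mode("rotation", np.pi / 4)
    assert np.allclose(R, _rot(np.pi / 4))
    assert np.linalg.det(R) == pytest.approx(1.0)

    F = deformation_mode("isochoric", 1.5)
    assert np.linalg.det(F) == pytest.approx(1.0)
    assert F[0, 0] == pytest.approx(1.5) and F[1, 1] == pytest.approx(1 / 1.5)
    # parameter alpha < 1: the larger stretch still lands on x by default
    F = deformation_mode("isochoric", 2 / 3)
    assert F[0, 0] == pytest.approx(1.5) and F[1, 1] == pytest.approx(2 / 3)
    F = deformation_mode("isochoric", 2 / 3, major_axis="as-given")
    assert F[0, 0] == pytest.approx(2 / 3)
    F = deformation_mode("isochoric", 1.5, major_axis="y")
    assert F[1, 1] == pytest.approx(1.5)

    F = deformation_mode("isotropic", 2.0)
    assert np.allclose(F, 2.0 * np.eye(2))
    assert np.linalg.det(F) == pytest.approx(4.0)

    with pytest.raises(ValueError):
        deformation_mode("shear", 1.0)


def test_segment_stretches():
    F = np.diag([2.0, 0.5])
    E = np.array([[1.0, 0.0], [0.0, 1.0], [np.sqrt(0.5), np.sqrt(0.5)]])
    eps = segment_stretches(E, F)
    assert eps[0] == pytest.approx(2.0)
    assert eps[1] == pytest.approx(0.5)
    assert eps[2] == pytest.approx(np.sqrt(0.5 * (4 + 0.25)))
    with pytest.raises(ValueError):
        segment_stretches(E, np.diag([1.0, -1.0]))


def test_vessel_radius_update_laws():
    # constant resistance: r = eps^(1/4) R; eps = 16 -> r = 2R
    assert vessel_radius_update(1.0, 16.0, law="const-resistance") == pytest.approx(2.0)
    # uniform porosity: r = sqrt(J phi_ratio / eps) R; eps=4, J=1, ratio=1 -> R/2
    assert vessel_radius_update(
        1.0, 4.0, J=1.0, phi_ratio=1.0, law="uniform-porosity"
    ) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        vessel_radius_update(1.0, 1.0, law="bogus")
    with pytest.raises(ValueError):
        vessel_radius_update(-1.0, 1.0)


def test_porosity_ratio_uniform_population():
    # identical radii/lengths: ratio = mean(eps^{3/2}) / J
    pop = generate_rve_population(RvePopulationSpec(n=2000, seed=5))
    F = np.diag([1.5, 1.0])
    eps = segment_stretches(pop.orientations, F)
    expected = np.mean(eps**1.5) / 1.5
    assert porosity_ratio(pop, F) == pytest.approx(expected, rel=1e-12)
    # rigid rotation preserves porosity exactly
    assert porosity_ratio(pop, _rot(0.3)) == pytest.approx(1.0, rel=1e-12)


def test_rehomogenize_identity_and_rotation(population_s1):
    pop = population_s1
    K0 = pop.permeability()
    assert np.allclose(rehomogenize(pop, np.eye(2), "const-resistance"), K0)
    assert np.allclose(rehomogenize(pop, np.eye(2), "uniform-porosity"), K0)
    R = _rot(np.pi / 4)
    for law in ("const-resistance", "uniform-porosity"):
        assert np.allclose(rehomogenize(pop, R, law), R @ K0 @ R.T, rtol=1e-12)


def test_rehomogenize_isotropic_invariance_const_resistance(population_s1):
    # isotropic stretch: eps = alpha everywhere, r = alpha^(1/4) R,
    # dl = alpha dL, |V| = alpha^2 |V_0|  =>  K unchanged
    pop = population_s1
    K0 = pop.permeability()
    F = deformation_mode("isotropic", 2 / 3)
    assert np.allclose(rehomogenize(pop, F, "const-resistance"), K0, rtol=1e-12)


def test_analytical_equals_vessel_rehomogenization():
    """Closed form J^-1 F K0 F^T is exact for the constant-resistance law."""
    rng = np.random.default_rng(42)
    for trial in range(5):
        pop = generate_rve_population(
            RvePopulationSpec(
                n=3000,
                phi_range=tuple(np.sort(rng.uniform(0, np.pi, 2))),
                seed=int(rng.integers(1 << 16)),
            )
        )
        F = np.eye(2) + rng.uniform(-0.4, 0.4, (2, 2))
        if np.linalg.det(F) <= 0.1:
            F = np.eye(2) + 0.3 * rng.random((2, 2))
        K_ref = rehomogenize(pop, F, "const-resistance")
        K_an = analytical_update(pop.permeability(), F)
        assert np.allclose(K_an, K_ref, rtol=1e-10, atol=1e-16)


def test_spectral_reconstruct_exact(population_s1):
    pop = population_s1
    K0 = pop.permeability()
    for spec in (
        SpectralPermeability.from_tensor(K0),
        SpectralPermeability.from_population(pop, n_bins=10),
        SpectralPermeability.from_population(pop, n_bins=1),
    ):
        assert np.allclose(spec.reconstruct(), K0, atol=1e-12 * np.trace(K0))


def test_spectral_update_identity_and_rotation(population_s1):
    pop = population_s1
    spec = SpectralPermeability.from_population(pop, n_bins=10)
    K0 = pop.permeability()
    assert np.allclose(spectral_update(spec, np.eye(2)), K0, rtol=1e-12)
    R = _rot(np.pi / 4)
    assert np.allclose(spectral_update(spec, R), R @ K0 @ R.T, rtol=1e-12)


def test_spectral_binned_tracks_uniform_rehomogenization(population_s1):
    """Isochoric stretch: binned spectral update stays close to the
    vessel-wise uniform-porosity oracle (strongly anisotropic population)."""
    pop = population_s1
    F = deformation_mode("isochoric", 1.5)
    ratio = porosity_ratio(pop, F)
    K_ref = rehomogenize(pop, F, "uniform-porosity", phi_ratio=ratio)
    spec = SpectralPermeability.from_population(pop, n_bins=10)
    K_fast = spectral_update(spec, F, phi_ratio=ratio)
    dev = np.abs(K_fast - K_ref) / np.abs(np.diag(K_ref)).max()
    assert dev.max() < 0.01


def test_spectral_cost_bound(population_s1):
    # the update touches at most n_bins eigen-systems, never the n segments
    spec = SpectralPermeability.from_population(population_s1, n_bins=10)
    assert spec.eigenvalues.shape == (10, 2)
    assert spec.eigenvectors.shape == (10, 2, 2)


def test_beta_update():
    assert beta_update(3.0, 1.5) == pytest.approx(2.0)
    assert np.allclose(beta_update([1.0, 2.0], 2.0), [0.5, 1.0])
    with pytest.raises(ValueError):
        beta_update(1.0, 0.0)


def test_pull_push_roundtrip():
    rng = np.random.default_rng(8)
    K = rng.random((2, 2))
    K = K @ K.T + 0.1 * np.eye(2)
    F = np.eye(2) + rng.uniform(-0.3, 0.3, (2, 2))
    assert np.allclose(push_forward_permeability(pull_back_permeability(K, F), F), K,
                       atol=1e-12)
    # isotropic F = 2I in 2D: J = 4 and F K F^T = 4 K  =>  push-forward is identity
    assert np.allclose(push_forward_permeability(K, 2 * np.eye(2)), K, atol=1e-14)
    # rigid rotation pull-back: K_0 = R^T K R
    R = _rot(0.7)
    assert np.allclose(pull_back_permeability(K, R), R.T @ K @ R, atol=1e-14)


def test_lagrangian_transform_fields():
    rng = np.random.default_rng(9)
    n = 7
    Ks = rng.random((n, 2, 2))
    Ks = Ks @ np.transpose(Ks, (0, 2, 1)) + 0.1 * np.eye(2)
    F = np.eye(2) + rng.uniform(-0.2, 0.2, (2, 2))
    K0 = lagrangian_transform(Ks, F, "permeability", "pull-back")
    back = lagrangian_transform(K0, F, "permeability", "push-forward")
    assert np.allclose(back, Ks, atol=1e-12)
    # scalar densities scale with J
    J = np.linalg.det(F)
    th = rng.random(n)
    assert np.allclose(
        lagrangian_transform(th, F, "source", "pull-back"), J * th
    )
    assert np.allclose(
        lagrangian_transform(th, F, "perfusion", "push-forward"), th / J
    )
    with pytest.raises(ValueError):
        lagrangian_transform(th, F, "source", "sideways")
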