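import numpy as np
import pytest

from perfusim import (
    DomainSpec,
    GenerationConfig,
    RvePopulationSpec,
    VascularTree,
    compute_flows,
    generate_rve_population,
    generate_tree,
    optimal_radii,
    rectangle_mesh,
)


@pytest.fixture
def tiny_tree():
    """Root -> bifurcation -> two leaves; 3 segments, 2 terminals."""
    pos = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 1.0], [2.0, -1.0]])
    parent = np.array([-1, 0, 1, 1])
    tree = VascularTree(pos, parent, q_perf=2.0, p_root=0.4)
    return optimal_radii(compute_flows(tree))


@pytest.fixture(scope="session")
def small_generated_tree():
    """A fully optimized 120-terminal tree in a disk (shared, read-only)."""
    domain = DomainSpec.disk(radius=5.0)
    cfg = GenerationConfig(
        n_term=120, root_position=(-4.5, 0.0), cooling_steps=15, seed=42
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return generate_tree(domain, cfg)


@pytest.fixture(scope="session")
def population_s1():
    return generate_rve_population(
        RvePopulationSpec(phi_range=(np.pi / 6, np.pi / 3), seed=101)
    )


@pytest.fixture(scope="session")
def population_s2():
    return generate_rve_population(RvePopulationSpec(phi_range=(0.0, np.pi), seed=101))


@pytest.fixture
def unit_square_mesh():
    return rectangle_mesh((0.0, 1.0, 0.0, 1.0), 8, 8)
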