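"""Benchmark drivers: permeability-update comparison tables and the
reduced-scale disk perfusion pipeline, plus field error metrics.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .compartments import compartmentalize
from .deform import (
    SpectralPermeability,
    analytical_update,
    deformation_mode,
    porosity_ratio,
    rehomogenize,
    spectral_update,
)
from .fem import (
    CompartmentModel,
    MultiCompartmentProblem,
    assemble,
    conservation_check,
    solve,
)
from .mesh import disk_mesh
from .population import SegmentPopulation, generate_rve_population
from .rve import HomogenizationConfig, homogenize_field, micro_permeability
from .synthesis import DomainSpec, GenerationConfig, generate_tree

__all__ = [
    "UPDATE_STRATEGIES",
    "BenchmarkReport",
    "run_update_benchmark",
    "DiskBenchmarkConfig",
    "DiskBenchmarkReport",
    "disk_benchmark",
    "reference_fields",
    "relative_l2",
    "field_histogram",
]

#: Fast strategies are compared against the re-homogenization oracle that
#: shares their radius law: uniform-porosity for the spectral family,
#: constant-resistance for the analytical closed form.
UPDATE_STRATEGIES = {
    "rehomog-uniform": "uniform-porosity",
    "rehomog-vessel": "const-resistance",
    "spectral": "uniform-porosity",
    "spectral-binned": "uniform-porosity",
    "analytical": "const-resistance",
}

DEFAULT_MODES = (
    ("rotation", "rotation", np.pi / 4),
    ("isochoric", "isochoric", 1.5),
    ("isotropic", "isotropic", 2.0 / 3.0),
)


def _components(K) -> dict:
    return {"K_xx": float(K[0, 0]), "K_xy": float(K[0, 1]), "K_yy": float(K[1, 1])}


@dataclass
class BenchmarkReport:
    undeformed: dict                 # tensor components of the initial state
    rows: list                       # one dict per (mode, strategy)
    population_n: int
    n_theta: int

    def row(self, mode: str, strategy: str) -> dict:
        for r in self.rows:
            if r["mode"] == mode and r["strategy"] == strategy:
                return r
        raise KeyError((mode, strategy))

    def to_table(self) -> str:
        hdr = f"{'mode':<12}{'strategy':<18}{'K_xx':>12}{'K_xy':>12}{'K_yy':>12}{'max dev %':>11}{'time ms':>9}"
        lines = [hdr, "-" * len(hdr)]
        u = self.undeformed
        lines.append(
            f"{'undeformed':<12}{'homogenization':<18}"
            f"{u['K_xx']:>12.4e}{u['K_xy']:>12.4e}{u['K_yy']:>12.4e}{'':>11}{'':>9}"
        )
        for r in self.rows:
            dev = max(r["deviation_pct"].values()) if r["deviation_pct"] else float("nan")
            lines.append(
                f"{r['mode']:<12}{r['strategy']:<18}"
                f"{r['K_xx']:>12.4e}{r['K_xy']:>12.4e}{r['K_yy']:>12.4e}"
                f"{dev:>11.3f}{1e3 * r['time_s']:>9.2f}"
            )
        return "\n".join(lines)


def run_update_benchmark(population: SegmentPopulation, modes=None,
                         strategies=None, n_theta: int = 10) -> BenchmarkReport:
    """Update-strategy comparison table for one segment population.

    ``modes``: list of (name, kind, parameter) triples (defaults:
    rotation pi/4, isochoric stretch 3/2, isotropic 2/3).  Timings are
    informational only — they depend on the machine, never on
    correctness.
    """
    modes = DEFAULT_MODES if modes is None else modes
    strategies = list(UPDATE_STRATEGIES) if strategies is None else strategies
    unknown = set(strategies) - set(UPDATE_STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")

    K0 = population.permeability()
    spectral_global = SpectralPermeability.from_tensor(K0)
    spectral_binned = SpectralPermeability.from_population(population, n_theta)

    rows = []
    for name, kind, param in modes:
        F = deformation_mode(kind, param)
        phi = porosity_ratio(population, F)
        oracle = {
            "uniform-porosity": rehomogenize(population, F, "uniform-porosity", phi),
            "const-resistance": rehomogenize(population, F, "const-resistance"),
        }
        for strat in strategies:
            t0 = time.perf_counter()
            if strat == "rehomog-uniform":
                K = rehomogenize(population, F, "uniform-porosity", phi)
            elif strat == "rehomog-vessel":
                K = rehomogenize(population, F, "const-resistance")
            elif strat == "spectral":
                K = spectral_update(spectral_global, F, phi)
            elif strat == "spectral-binned":
                K = spectral_update(spectral_binned, F, phi)
            else:
                K = analytical_update(K0, F)
            dt = time.perf_counter() - t0
            ref = oracle[UPDATE_STRATEGIES[strat]]
            scale = max(abs(ref).max(), 1e-300)
            dev = {
                key: 100.0 * abs(Kc - Rc) / max(abs(Rc), 1e-6 * scale)
                for key, Kc, Rc in zip(
                    ("K_xx", "K_xy", "K_yy"),
                    (K[0, 0], K[0, 1], K[1, 1]),
                    (ref[0, 0], ref[0, 1], ref[1, 1]),
                )
            }
            rows.append(
                {"mode": name, "strategy": strat, **_components(K),
                 "deviation_pct": dev, "time_s": dt}
            )
    return BenchmarkReport(
        undeformed=_components(K0), rows=rows,
        population_n=population.n, n_theta=n_theta,
    )


# -- disk perfusion benchmark ----------------------------------------------


@dataclass
class DiskBenchmarkConfig:
    """Reduced-scale two-tree disk perfusion study.

    Defaults run the full pipeline (synthesis -> compartments ->
    homogenization -> FEM) in minutes on one CPU.
    """

    disk_radius: float = 10.0        # mm
    n_term: int = 500                # terminals per tree
    q_perf: float = 80.0             # mm^3/s
    p_root_supply: float = 0.4       # kPa-scale units (kg mm^-1 s^-2)
    p_root_drain: float = 0.0
    m_b: float = 0.6
    eta: float = 3.6e-6
    r_threshold: float = 0.25        # mm, resolved/homogenized split
    mesh_edge: float = 0.5           # mm
    rve_radius: float = 1.0          # mm
    sigma: float = 0.6               # mm
    k_micro: float = 2e-8            # mm^2
    degree: int = 1
    seed: int = 0
    cooling_steps: int = 40


@dataclass
class DiskBenchmarkReport:
    mass_residual: float
    total_supplied: float
    total_drained: float
    energy: float
    mean_pressures: dict
    velocity_medians: dict
    velocity_ratio_micro_tree: float
    stage_times: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"supplied flow      : {self.total_supplied:.4f} mm^3/s",
            f"drained flow       : {self.total_drained:.4f} mm^3/s",
            f"mass residual      : {self.mass_residual:.3e}",
            f"energy functional  : {self.energy:.4e} uW",
            "mean pressures     : "
            + ", ".join(f"{k}={v:.4f}" for k, v in self.mean_pressures.items()),
            "median |w|         : "
            + ", ".join(f"{k}={v:.3e}" for k, v in self.velocity_medians.items()),
            f"micro/tree |w|     : {self.velocity_ratio_micro_tree:.3e}",
        ]
        for k, v in self.stage_times.items():
            lines.append(f"time {k:<14}: {v:.2f} s")
        return "\n".join(lines)


def disk_benchmark(config: Optional[DiskBenchmarkConfig] = None):
    """Full two-tree disk pipeline; returns (solution, report, context).

    ``context`` carries the intermediate artifacts (trees, schemes, mesh,
    parameter fields) for inspection and export.
    """
    cfg = config or DiskBenchmarkConfig()
    times = {}
    domain = DomainSpec.disk(radius=cfg.disk_radius)
    roots = {
        "supplying": np.array([-0.95 * cfg.disk_radius, 0.0]),
        "draining": np.array([0.95 * cfg.disk_radius, 0.0]),
    }
    trees = []
    t0 = time.perf_counter()
    for j, role in enumerate(("supplying", "draining")):
        gen = GenerationConfig(
            n_term=cfg.n_term,
            root_position=roots[role],
            q_perf=cfg.q_perf,
            p_root=cfg.p_root_supply if role == "supplying" else cfg.p_root_drain,
            m_b=cfg.m_b,
            eta=cfg.eta,
            role=role,
            cooling_steps=cfg.cooling_steps,
            seed=cfg.seed + 17 * (j + 1),
        )
        trees.append(generate_tree(domain, gen))
    times["synthesis"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    thresholds = np.array([cfg.r_threshold, 0.0])
    schemes = [compartmentalize(t, thresholds) for t in trees]
    mesh = disk_mesh(cfg.disk_radius, cfg.mesh_edge)
    hcfg = HomogenizationConfig(
        rve_radius=cfg.rve_radius, sigma=cfg.sigma, seed=cfg.seed
    )
    perm, coupling, sources = homogenize_field(schemes, mesh, hcfg, domain=domain)
    times["homogenization"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    K_micro = micro_permeability(cfg.eta, k_micro=cfg.k_micro)
    n_cells = mesh.n_cells
    supply = CompartmentModel(
        name="supply", K=perm[0][1].K, source=sources[0]
    )
    drain = CompartmentModel(
        name="drain",
        K=perm[1][1].K,
        sink_beta=coupling[1].beta_outflow,
        sink_pressure=coupling[1].p_outflow,
    )
    micro = CompartmentModel(
        name="micro", K=np.tile(K_micro * np.eye(2), (n_cells, 1, 1))
    )
    problem = MultiCompartmentProblem(
        mesh=mesh,
        compartments=[supply, drain, micro],
        couplings={
            (0, 2): coupling[0].beta_terminal,
            (1, 2): coupling[1].beta_terminal,
        },
        degree=cfg.degree,
    )
    system = assemble(problem)
    solution = solve(system)
    times["fem"] = time.perf_counter() - t0

    checks = conservation_check(solution)
    vmed = {
        c.name: float(np.median(np.linalg.norm(solution.darcy_velocity(i), axis=1)))
        for i, c in enumerate(problem.compartments)
    }
    tree_med = max(vmed["supply"], vmed["drain"])
    report = DiskBenchmarkReport(
        mass_residual=checks["mass_residual"],
        total_supplied=checks["total_source"],
        total_drained=checks["sink_outflow"],
        energy=checks["energy"],
        mean_pressures={
            c.name: solution.mean_pressure(i)
            for i, c in enumerate(problem.compartments)
        },
        velocity_medians=vmed,
        velocity_ratio_micro_tree=vmed["micro"] / tree_med if tree_med > 0 else np.nan,
        stage_times=times,
    )
    context = {
        "trees": trees,
        "schemes": schemes,
        "mesh": mesh,
        "permeability": perm,
        "coupling": coupling,
        "sources": sources,
        "problem": problem,
        "config": cfg,
    }
    return solution, report, context


# -- field error metrics ---------------------------------------------------


def reference_fields(beta, p_avg, p_micro, q_perf, mesh) -> np.ndarray:
    """Normalized microcirculation inflow field.

    q_avg = beta (p_avg - p_micro) * q_perf / int beta (p_avg - p_micro) dOmega,
    so that the field integrates exactly to q_perf.
    """
    beta = np.asarray(beta, float)
    raw = beta * (np.asarray(p_avg, float) - p_micro)
    denom = float(np.sum(raw * mesh.cell_areas()))
    if denom == 0.0:
        raise ValueError("zero net exchange; reference field undefined")
    return raw * (q_perf / denom)


def relative_l2(values, reference, mesh) -> float:
    """Volume-weighted relative L2 distance of two per-cell fields."""
    v = np.asarray(values, float)
    r = np.asarray(reference, float)
    w = mesh.cell_areas()
    ref_norm = np.sqrt(np.sum(w * r**2))
    if ref_norm == 0.0:
        raise ValueError("reference field has zero norm")
    return float(np.sqrt(np.sum(w * (v - r) ** 2)) / ref_norm)


def field_histogram(values, mesh, bins=20, value_range=None):
    """Volume-weighted relative-frequency histogram of a per-cell field."""
    v = np.asarray(values, float)
    w = mesh.cell_areas()
    hist, edges = np.histogram(v, bins=bins, range=value_range, weights=w)
    return hist / w.sum(), edges
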