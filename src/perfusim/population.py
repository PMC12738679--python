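"""Synthetic segment populations for permeability-update benchmarks.

A population is a cloud of straight segments with fixed radius, length
and viscosity inside a fixed averaging volume; only the orientations are
random.  Two stock orientation laws: uniform on a sub-interval
[phi_min, phi_max] (anisotropic) and uniform on [0, pi) (isotropic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .rve import permeability_tensor

__all__ = ["RvePopulationSpec", "SegmentPopulation", "generate_rve_population"]


@dataclass
class RvePopulationSpec:
    n: int = 100_000
    radius: float = 0.01
    length: float = 0.01
    eta: float = 1e-6
    phi_range: tuple = (0.0, np.pi)
    volume: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n, self.radius, self.length, self.eta, self.volume) <= 0:
            raise ValueError("population parameters must be positive")


@dataclass
class SegmentPopulation:
    """Reference-configuration segment cloud inside one averaging volume."""

    radii: np.ndarray          # R_a (mm)
    lengths: np.ndarray        # dL_a (mm)
    angles: np.ndarray         # undirected orientation angle in [0, pi)
    viscosities: np.ndarray
    volume: float              # |V_0|
    spec: Optional[RvePopulationSpec] = None

    @property
    def n(self) -> int:
        return len(self.radii)

    @property
    def orientations(self) -> np.ndarray:
        """Unit vectors E_a, shape (n, 2)."""
        return np.column_stack([np.cos(self.angles), np.sin(self.angles)])

    def permeability(self) -> np.ndarray:
        """Homogenized tensor of the undeformed population."""
        return permeability_tensor(
            self.radii, self.lengths, self.viscosities,
            self.orientations, self.volume,
        )


def generate_rve_population(spec: RvePopulationSpec) -> SegmentPopulation:
    """Draw orientations uniformly on ``spec.phi_range``; seed-reproducible."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.phi_range
    angles = np.mod(rng.uniform(lo, hi, spec.n), np.pi)
    return SegmentPopulation(
        radii=np.full(spec.n, spec.radius),
        lengths=np.full(spec.n, spec.length),
        angles=angles,
        viscosities=np.full(spec.n, spec.eta),
        volume=spec.volume,
        spec=spec,
    )
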