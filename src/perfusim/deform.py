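"""Deformation-dependent update of homogenized perfusion parameters.

Given a (cellwise-constant) deformation gradient F with J = det F > 0,
the permeability of a deforming vessel population can be updated by

* full vessel-wise re-homogenization (the accuracy oracle): map every
  segment E -> e = F E/|F E|, dL -> eps dL, R -> r by a radius law,
  |V_0| -> J |V_0|, and re-apply the averaging sum;
* the spectral update: eigendecomposition of the initial tensor (per
  orientation bin or global), each eigen-direction treated as one
  representative segment bundle,
      K = (J phi^2/phi_0^2) F [sum_n lam_n eps_n^-3 Lam_n (x) Lam_n] F^T,
  with eps_n = |F Lam_n|; cost independent of the segment count;
* the analytical constant-resistance update K = J^-1 F K|0 F^T, exact
  (not approximate) under the constant-resistance radius law.

Radius laws: "const-resistance" keeps every segment's hydraulic
resistance fixed, r = eps^(1/4) R; "uniform-porosity" redistributes the
compartment porosity equally over all vessels,
r = (J phi/(eps phi_0))^(1/2) R.

Perfusion coefficients scale inversely with volume change, beta = beta_0/J.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .rve import permeability_tensor

__all__ = [
    "deformation_mode",
    "segment_stretches",
    "vessel_radius_update",
    "porosity_ratio",
    "rehomogenize",
    "SpectralPermeability",
    "spectral_update",
    "analytical_update",
    "beta_update",
    "pull_back_permeability",
    "push_forward_permeability",
    "lagrangian_transform",
]

RADIUS_LAWS = ("uniform-porosity", "const-resistance")


def deformation_mode(kind: str, parameter: float, *, major_axis: str = "x"):
    """Stock 2D deformation gradients.

    kind = "rotation": parameter is the angle psi (rad).
    kind = "isochoric": principal stretches {alpha, 1/alpha}; the larger
    of the two goes on the ``major_axis`` ("x" by default, "y" to flip,
    "as-given" to use diag(alpha, 1/alpha) literally).
    kind = "isotropic": alpha * I.
    """
    if kind == "rotation":
        c, s = np.cos(parameter), np.sin(parameter)
        return np.array([[c, -s], [s, c]])
    if parameter <= 0:
        raise ValueError("stretch parameter must be positive")
    if kind == "isotropic":
        return parameter * np.eye(2)
    if kind == "isochoric":
        a, b = parameter, 1.0 / parameter
        if major_axis == "x":
            a, b = max(a, b), min(a, b)
        elif major_axis == "y":
            a, b = min(a, b), max(a, b)
        elif major_axis != "as-given":
            raise ValueError("major_axis must be 'x', 'y' or 'as-given'")
        return np.diag([a, b])
    raise ValueError(f"unknown deformation kind {kind!r}")


def _check_F(F):
    F = np.asarray(F, float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    return F, J


def segment_stretches(orientations, F) -> np.ndarray:
    """eps_a = |F E_a| for unit reference orientations E_a."""
    F, _ = _check_F(F)
    return np.linalg.norm(orientations @ F.T, axis=-1)


def vessel_radius_update(R, eps, J=1.0, phi_ratio=1.0, law="uniform-porosity"):
    """Deformed vessel radius r from the reference radius R."""
    R = np.asarray(R, float)
    eps = np.asarray(eps, float)
    if np.any(R <= 0) or np.any(eps <= 0):
        raise ValueError("radii and stretches must be positive")
    if law == "const-resistance":
        return eps**0.25 * R
    if law == "uniform-porosity":
        return np.sqrt(J * phi_ratio / eps) * R
    raise ValueError(f"unknown radius law {law!r}")


def porosity_ratio(population, F) -> float:
    """phi/phi_0 = (sum R^2 eps^(3/2) dL) / (J sum R^2 dL).

    The vessel volume fraction implied by the constant-resistance law
    (r^2 dl = eps^(3/2) R^2 dL) relative to the deformed bulk volume.
    """
    F, J = _check_F(F)
    eps = segment_stretches(population.orientations, F)
    R2L = population.radii**2 * population.lengths
    return float(np.sum(R2L * eps**1.5) / (J * np.sum(R2L)))


def rehomogenize(population, F, law="uniform-porosity",
                 phi_ratio: Optional[float] = None) -> np.ndarray:
    """Vessel-wise re-homogenization: the accuracy oracle for fast updates."""
    if law not in RADIUS_LAWS:
        raise ValueError(f"unknown radius law {law!r}")
    F, J = _check_F(F)
    E = population.orientations
    eps = segment_stretches(E, F)
    e = (E @ F.T) / eps[:, None]
    if law == "uniform-porosity" and phi_ratio is None:
        phi_ratio = porosity_ratio(population, F)
    r = vessel_radius_update(
        population.radii, eps, J=J,
        phi_ratio=1.0 if phi_ratio is None else phi_ratio, law=law,
    )
    return permeability_tensor(
        r, eps * population.lengths, population.viscosities, e,
        J * population.volume,
    )


@dataclass
class SpectralPermeability:
    """Eigendecomposition of an initial permeability tensor.

    Either a single global decomposition or one per orientation bin
    (equal-width intervals of the undirected angle in [0, pi)); the bin
    tensors sum to the total tensor.
    """

    eigenvalues: np.ndarray      # (n_bins, d)
    eigenvectors: np.ndarray     # (n_bins, d, d), columns are Lam_n
    n_bins: int = 1

    def __post_init__(self):
        if np.any(self.eigenvalues < -1e-12 * max(self.eigenvalues.max(), 1e-300)):
            raise ValueError("cached permeability tensor is not PSD")
        self.eigenvalues = np.maximum(self.eigenvalues, 0.0)

    @classmethod
    def from_tensor(cls, K) -> "SpectralPermeability":
        lam, vec = np.linalg.eigh(np.asarray(K, float))
        return cls(lam[None, :], vec[None, :, :], n_bins=1)

    @classmethod
    def from_population(cls, population, n_bins: int = 10,
                        angle_range=None) -> "SpectralPermeability":
        """Per-orientation-bin decomposition of the population's tensor.

        Bins are equal-width intervals of the undirected segment angle.
        By default they partition the population's occupied orientation
        domain [min angle, max angle]; narrow orientation distributions
        thus get proportionally narrower bins, which is what makes the
        binned update accurate for strongly anisotropic populations.
        Pass ``angle_range=(0, np.pi)`` for fixed full-range bins.
        """
        if angle_range is None:
            angle_range = (population.angles.min(), population.angles.max())
        lo, hi = angle_range
        if hi <= lo:
            raise ValueError("empty orientation range")
        edges = np.linspace(lo, hi, n_bins + 1)
        which = np.clip(np.digitize(population.angles, edges) - 1, 0, n_bins - 1)
        lam = np.zeros((n_bins, 2))
        vec = np.tile(np.eye(2), (n_bins, 1, 1))
        for m in range(n_bins):
            sel = which == m
            if not np.any(sel):
                continue
            Km = permeability_tensor(
                population.radii[sel], population.lengths[sel],
                population.viscosities[sel], population.orientations[sel],
                population.volume,
            )
            lam[m], vec[m] = np.linalg.eigh(Km)
        return cls(lam, vec, n_bins=n_bins)

    def reconstruct(self) -> np.ndarray:
        """Sum lam_n Lam_n (x) Lam_n over all bins (the cached tensor)."""
        return np.einsum(
            "mn,min,mjn->ij", self.eigenvalues, self.eigenvectors, self.eigenvectors
        )


def spectral_update(spectral: SpectralPermeability, F, phi_ratio=1.0):
    """K = (J phi^2/phi_0^2) F [sum lam_n eps_n^-3 Lam_n (x) Lam_n] F^T per bin.

    ``phi_ratio`` may be a scalar (global porosity ratio, the
    uniform-porosity law) or one value per orientation bin.
    """
    F, J = _check_F(F)
    ratios = np.broadcast_to(np.asarray(phi_ratio, float), (spectral.n_bins,))
    K = np.zeros((2, 2))
    for m in range(spectral.n_bins):
        lam = spectral.eigenvalues[m]
        vec = spectral.eigenvectors[m]
        eps = np.linalg.norm(F @ vec, axis=0)
        core = (vec * (lam / eps**3)) @ vec.T
        K += ratios[m] ** 2 * (F @ core @ F.T)
    K *= J
    return 0.5 * (K + K.T)


def analytical_update(K0, F) -> np.ndarray:
    """Constant-resistance closed form K = J^-1 F K|0 F^T (exact)."""
    F, J = _check_F(F)
    K0 = np.asarray(K0, float)
    K = F @ K0 @ F.T / J
    return 0.5 * (K + K.T)


def beta_update(beta0, J):
    """beta = beta_0 / J (perfusion coefficients scale inversely with volume)."""
    if np.any(np.asarray(J) <= 0):
        raise ValueError("J must be positive")
    return np.asarray(beta0, float) / J


def pull_back_permeability(K, F) -> np.ndarray:
    """K_0 = J F^-1 K F^-T."""
    F, J = _check_F(F)
    Fi = np.linalg.inv(F)
    return J * (Fi @ np.asarray(K, float) @ Fi.T)


def push_forward_permeability(K0, F) -> np.ndarray:
    """K = J^-1 F K_0 F^T."""
    F, J = _check_F(F)
    return (F @ np.asarray(K0, float) @ F.T) / J


def lagrangian_transform(field, F, quantity="permeability", direction="pull-back"):
    """Transform a parameter field between configurations.

    ``field`` may be a single value or a per-cell stack; ``F`` a single
    2x2 gradient or a matching (n, 2, 2) stack.  Scalars transform as
    densities: theta_0 = J theta, beta_0 = J beta (and the inverses for
    push-forward).
    """
    if direction not in ("pull-back", "push-forward"):
        raise ValueError("direction must be 'pull-back' or 'push-forward'")
    F = np.asarray(F, float)
    field = np.asarray(field, float)
    single_F = F.ndim == 2
    Fs = F[None] if single_F else F
    J = np.linalg.det(Fs)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    if quantity == "permeability":
        single = field.ndim == 2
        Ks = field[None] if single else field
        if direction == "pull-back":
            Fi = np.linalg.inv(Fs)
            out = J[:, None, None] * np.einsum("cij,cjk,clk->cil", Fi, Ks, Fi)
        else:
            out = np.einsum("cij,cjk,clk->cil", Fs, Ks, Fs) / J[:, None, None]
        return out[0] if single else out
    if quantity in ("source", "perfusion"):
        Jv = J[0] if single_F else J
        return field * Jv if direction == "pull-back" else field / Jv
    raise ValueError(f"unknown quantity {quantity!r}")
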