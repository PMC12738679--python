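"""RVE averaging: permeability tensors, perfusion coefficients, sources.

Continuum parameters of each homogenized compartment are estimated by
averaging the discrete Poiseuille network over a representative volume
element (RVE) — a ball (circle in 2D) centered at each mesh-cell
centroid.  The key formulas:

* permeability (current configuration)
      K_i = pi / (8 |V|) * sum_a  r_a^4 dl_a / eta_a  (e_a ⊗ e_a)
  where dl_a is the clipped in-RVE length of segment a and e_a its unit
  orientation;
* intercompartmental perfusion coefficient
      beta_{i,k} = <q_{i,k}> / |<p>*_i - <p>*_k|,
      <q_{i,k}> = (1/|V|) * sum of interface-segment flows whose
      upstream node lies in the RVE,
  with <p>*_i the vessel-volume weighted average pressure;
* Gaussian source fields that smear the outlet flows of the resolved
  upper hierarchy over the domain with spread sigma.

RVEs that overlap the domain boundary keep all their vessels but use the
clipped (effective) volume, in the spirit of a fictitious-domain method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .compartments import CompartmentScheme
from .geometry import clip_segments_to_ball, disk_disk_overlap_area
from .synthesis import DomainSpec
from .tree import node_pressures

__all__ = [
    "RveSpec",
    "ClippedSegment",
    "clip_segment_to_rve",
    "permeability_tensor",
    "segment_average_pressure",
    "compartment_average_pressure",
    "perfusion_coefficient",
    "micro_permeability",
    "SourceField",
    "PermeabilityField",
    "PerfusionCoupling",
    "HomogenizationConfig",
    "homogenize_field",
]


@dataclass
class RveSpec:
    """Ball-shaped averaging volume.

    ``effective_volume`` is the measure of the intersection with the
    perfusion domain (<= nominal volume); in 2D "volume" means area.
    """

    center: np.ndarray
    radius: float
    dim: int = 2
    effective_volume: Optional[float] = None

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        if self.radius <= 0:
            raise ValueError("RVE radius must be positive")
        if self.effective_volume is None:
            self.effective_volume = self.nominal_volume
        if self.effective_volume <= 0 or self.effective_volume > self.nominal_volume * (1 + 1e-9):
            raise ValueError("effective volume must lie in (0, nominal volume]")

    @property
    def nominal_volume(self) -> float:
        if self.dim == 2:
            return float(np.pi * self.radius**2)
        return float(4.0 / 3.0 * np.pi * self.radius**3)


@dataclass
class ClippedSegment:
    """The part of one vessel segment inside an RVE."""

    segment: int
    s1: float
    s2: float
    x1: np.ndarray
    x2: np.ndarray

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.x2 - self.x1))

    @property
    def orientation(self) -> np.ndarray:
        d = self.x2 - self.x1
        n = np.linalg.norm(d)
        return d / n if n > 0 else d

    @property
    def s_mid(self) -> float:
        return 0.5 * (self.s1 + self.s2)


def clip_segment_to_rve(x_u, x_v, rve: RveSpec, segment_id: int = 0):
    """Maximal sub-interval of the segment inside the RVE ball, or None."""
    x_u = np.asarray(x_u, float)
    x_v = np.asarray(x_v, float)
    s1, s2, ok = clip_segments_to_ball(
        x_u[None, :], x_v[None, :], rve.center, rve.radius
    )
    if not ok[0]:
        return None
    g = lambda s: (1 - s) * x_u + s * x_v
    return ClippedSegment(segment_id, float(s1[0]), float(s2[0]), g(s1[0]), g(s2[0]))


def permeability_tensor(radii, lengths, viscosities, orientations, volume, dim=2):
    """K = pi/(8 |V|) * sum_a r^4 dl / eta * (e ⊗ e); symmetric PSD by construction."""
    if volume <= 0:
        raise ValueError("RVE volume must be positive")
    r = np.asarray(radii, float)
    dl = np.asarray(lengths, float)
    eta = np.broadcast_to(np.asarray(viscosities, float), r.shape)
    e = np.atleast_2d(np.asarray(orientations, float))[:, :dim]
    if len(r) == 0:
        return np.zeros((dim, dim))
    w = r**4 * dl / eta
    K = np.einsum("a,ai,aj->ij", w, e, e) * (np.pi / (8.0 * volume))
    return 0.5 * (K + K.T)


def segment_average_pressure(s1, s2, p_u, p_v):
    """In-RVE average pressure of a straight segment with linear pressure drop."""
    m = 0.5 * (np.asarray(s1, float) + np.asarray(s2, float))
    return (1.0 - m) * p_u + m * p_v


def compartment_average_pressure(radii, lengths, seg_avg_pressures):
    """Vessel-volume weighted (V_a = pi r^2 dl) mean of segment averages.

    Returns None for an empty segment set (the caller forces beta = 0).
    """
    r = np.asarray(radii, float)
    if len(r) == 0:
        return None
    v = np.pi * r**2 * np.asarray(lengths, float)
    tot = v.sum()
    if tot <= 0:
        return None
    return float(np.sum(v * np.asarray(seg_avg_pressures, float)) / tot)


def perfusion_coefficient(q_avg: float, p_i, p_k) -> float:
    """beta = <q> / |<p>*_i - <p>*_k|, zero for empty interfaces or zero gap."""
    if p_i is None or p_k is None:
        return 0.0
    gap = abs(p_i - p_k)
    if gap == 0.0 or q_avg == 0.0:
        return 0.0
    return abs(q_avg) / gap


def micro_permeability(eta: float, k_micro: Optional[float] = None,
                       d_char: Optional[float] = None,
                       phi_micro: Optional[float] = None) -> float:
    """Scalar microcirculatory permeability K_micro = k_micro / eta.

    The intrinsic permeability is either given directly (mm^2) or derived
    from the Kozeny-Carman relation k = d^2 phi^3 / (1 - phi^2) with a
    characteristic pore length d (mm) and micro porosity phi.
    """
    if k_micro is None:
        if d_char is None or phi_micro is None:
            raise ValueError("provide k_micro or (d_char, phi_micro)")
        if not (0.0 < phi_micro < 1.0):
            raise ValueError("micro porosity must lie in (0, 1)")
        k_micro = d_char**2 * phi_micro**3 / (1.0 - phi_micro**2)
    if k_micro <= 0 or eta <= 0:
        raise ValueError("permeability and viscosity must be positive")
    return k_micro / eta


class SourceField:
    """Sum of flow-weighted isotropic Gaussians centered at outlet nodes.

    theta(x) = sum_u Q_u (2 pi sigma^2)^(-d/2) exp(-|x - x_u|^2/(2 sigma^2)).
    Negative weights model drainage.
    """

    def __init__(self, outlets, flows, sigma: float, dim: int = 2):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.outlets = np.atleast_2d(np.asarray(outlets, float))
        self.flows = np.asarray(flows, float)
        self.sigma = float(sigma)
        self.dim = int(dim)
        self._norm = (2.0 * np.pi * sigma**2) ** (-dim / 2.0)

    def __call__(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))[:, : self.dim]
        d2 = ((x[:, None, :] - self.outlets[None, :, : self.dim]) ** 2).sum(axis=2)
        return self._norm * (self.flows[None, :] * np.exp(
            -0.5 * d2 / self.sigma**2
        )).sum(axis=1)

    @property
    def total_flow(self) -> float:
        """Analytic integral over all of R^d."""
        return float(self.flows.sum())


@dataclass
class PermeabilityField:
    """Per-cell symmetric permeability tensors of one compartment."""

    K: np.ndarray               # (n_cells, d, d)
    floored: np.ndarray         # (n_cells,) bool
    configuration: str = "current"
    floor_value: float = 0.0


@dataclass
class PerfusionCoupling:
    """Per-cell coupling data of one tree.

    ``beta_terminal``/``p_out_terminal``: coupling of the lowest
    compartment to the microcirculation via the terminal segments.
    ``beta_internal``: tree-internal couplings keyed by compartment pair.
    ``beta_outflow``/``p_outflow``: pressure-dependent sink of a draining
    tree toward its resolved hierarchy.
    """

    beta_terminal: np.ndarray
    p_out_terminal: np.ndarray
    beta_internal: dict = field(default_factory=dict)
    beta_outflow: Optional[np.ndarray] = None
    p_outflow: Optional[np.ndarray] = None


@dataclass
class HomogenizationConfig:
    rve_radius: float = 1.0
    sigma: float = 0.6
    floor_rel: float = 1e-6
    p_ref_micro: Optional[float] = None
    mc_samples: int = 10_000
    seed: int = 0


def _effective_volumes(mesh, domain: Optional[DomainSpec], rho: float,
                       cfg: HomogenizationConfig) -> np.ndarray:
    """Domain-clipped RVE measures at all cell centroids."""
    cent = mesh.centroids()
    nominal = np.pi * rho * rho
    if domain is None:
        return np.full(len(cent), nominal)
    if domain.kind == "disk":
        c = np.asarray(domain.params["center"], float)
        R = domain.params["radius"]
        d = np.linalg.norm(cent - c, axis=1)
        return np.array([disk_disk_overlap_area(R, rho, di) for di in d])
    # Monte-Carlo fallback for rectangles / mesh-bounded domains
    rng = np.random.default_rng(cfg.seed)
    n = cfg.mc_samples
    u = rng.random(n)
    theta = rng.random(n) * 2 * np.pi
    pts = np.sqrt(u)[:, None] * rho * np.column_stack([np.cos(theta), np.sin(theta)])
    out = np.empty(len(cent))
    for k, x in enumerate(cent):
        out[k] = nominal * domain.contains(x[None, :] + pts).mean()
    return out


class _TreeArrays:
    """Flat per-segment arrays of one compartmentalized tree (homogenized part)."""

    def __init__(self, scheme: CompartmentScheme):
        tree = scheme.tree
        self.scheme = scheme
        self.tree = tree
        p = node_pressures(tree)
        self.node_p = p
        pos = tree.positions[:, :2] if tree.dim == 2 else tree.positions
        self.x_u = pos[tree.proximal]
        self.x_v = pos[tree.distal]
        self.mid = 0.5 * (self.x_u + self.x_v)
        self.half = 0.5 * np.linalg.norm(self.x_v - self.x_u, axis=1)
        self.kd = cKDTree(self.mid)
        self.p_u = p[tree.proximal]
        self.p_v = p[tree.distal]
        self.leaf_seg = tree._seg_of_node[tree.leaves]
        self.leaf_pos = pos[tree.leaves]
        self.leaf_p = p[tree.leaves]
        self.leaf_kd = cKDTree(self.leaf_pos) if len(self.leaf_pos) else None

    def candidates(self, center, rho):
        idx = self.kd.query_ball_point(center, rho + self.half.max())
        idx = np.asarray(idx, dtype=np.int64)
        if len(idx):
            keep = (
                np.linalg.norm(self.mid[idx] - center, axis=1)
                <= rho + self.half[idx]
            )
            idx = idx[keep]
        return idx


def homogenize_field(schemes, mesh, config: HomogenizationConfig,
                     domain: Optional[DomainSpec] = None):
    """Estimate all continuum parameters on a mesh, one RVE per cell.

    Parameters
    ----------
    schemes : list of CompartmentScheme
        One compartmentalized tree per entry (supplying and/or draining).
    mesh : TriMesh
    config : HomogenizationConfig
    domain : DomainSpec, optional
        Used to clip boundary RVE volumes; None keeps nominal volumes.

    Returns
    -------
    perm : list of dict
        Per tree: compartment index -> PermeabilityField.
    coupling : list of PerfusionCoupling
        Per tree.
    sources : list of SourceField
        Per tree (outlets of the resolved hierarchy into compartment 1).
    """
    if mesh.n_cells == 0:
        raise ValueError("empty mesh")
    rho = config.rve_radius
    cent = mesh.centroids()
    vols = _effective_volumes(mesh, domain, rho, config)
    n_cells = mesh.n_cells

    perm, coupling, sources = [], [], []
    for scheme in schemes:
        arr = _TreeArrays(scheme)
        tree = scheme.tree
        ncomp = scheme.n_compartments
        seg_comp = scheme.segment_compartment
        K_cells = {i: np.zeros((n_cells, 2, 2)) for i in range(1, ncomp + 1)}
        p_avg = {i: np.full(n_cells, np.nan) for i in range(1, ncomp + 1)}
        beta_term = np.zeros(n_cells)
        p_out_term = np.full(n_cells, np.nan)
        beta_internal = {
            (i, i + 1): np.zeros(n_cells) for i in range(1, ncomp)
        }
        # resolved -> compartment-1 outlet nodes (sources / outflow sinks)
        out_nodes, out_flows = scheme.outlet_nodes(1)
        out_pos = tree.positions[out_nodes, :2]
        out_p = arr.node_p[out_nodes]
        out_kd = cKDTree(out_pos) if len(out_pos) else None
        beta_outflow = np.zeros(n_cells) if tree.role == "draining" else None
        p_outflow = np.full(n_cells, np.nan) if tree.role == "draining" else None

        leaf_comp = ncomp  # terminals live in the lowest compartment

        for c in range(n_cells):
            x = cent[c]
            vol = vols[c]
            if vol <= 0.0:
                # RVE entirely outside the perfusion domain: no vessels,
                # parameters stay at their empty defaults (floored later)
                continue
            cand = arr.candidates(x, rho)
            if len(cand):
                s1, s2, ok = clip_segments_to_ball(
                    arr.x_u[cand], arr.x_v[cand], x, rho
                )
                cand = cand[ok]
                s1, s2 = s1[ok], s2[ok]
            if len(cand) == 0:
                s1 = s2 = np.empty(0)
            dvec = arr.x_v[cand] - arr.x_u[cand]
            full_len = np.linalg.norm(dvec, axis=1)
            dl = (s2 - s1) * full_len
            with np.errstate(invalid="ignore"):
                e = dvec / np.where(full_len > 0, full_len, 1.0)[:, None]
            p_seg = segment_average_pressure(
                s1, s2, arr.p_u[cand], arr.p_v[cand]
            )
            for i in range(1, ncomp + 1):
                m = seg_comp[cand] == i
                K_cells[i][c] = permeability_tensor(
                    tree.radii[cand[m]], dl[m],
                    tree.viscosities[cand[m]], e[m], vol,
                )
                pa = compartment_average_pressure(
                    tree.radii[cand[m]], dl[m], p_seg[m]
                )
                p_avg[i][c] = np.nan if pa is None else pa

            # tree-internal couplings between consecutive compartments
            for (i, k), segs in scheme.interfaces.items():
                if not (1 <= i <= ncomp and 1 <= k <= ncomp and i < k):
                    continue
                inside = (
                    np.linalg.norm(arr.x_u[segs] - x, axis=1) <= rho
                )
                q_avg = tree.flows[segs[inside]].sum() / vol
                pi_, pk_ = p_avg[i][c], p_avg[k][c]
                b = perfusion_coefficient(
                    q_avg,
                    None if np.isnan(pi_) else pi_,
                    None if np.isnan(pk_) else pk_,
                )
                if (i, k) in beta_internal:
                    beta_internal[(i, k)][c] = b

            # terminal coupling to the microcirculation
            if arr.leaf_kd is not None:
                lidx = arr.leaf_kd.query_ball_point(x, rho)
                if lidx:
                    lidx = np.asarray(lidx)
                    q_avg = tree.flows[arr.leaf_seg[lidx]].sum() / vol
                    p_out = float(arr.leaf_p[lidx].mean())
                    p_out_term[c] = p_out
                    pN = p_avg[leaf_comp][c]
                    gap = abs(pN - p_out) if not np.isnan(pN) else 0.0
                    if gap <= 1e-12 * max(abs(tree.p_root), 1.0):
                        if config.p_ref_micro is not None:
                            gap = abs(p_out - config.p_ref_micro)
                        else:
                            gap = 0.0
                    beta_term[c] = abs(q_avg) / gap if gap > 0 else 0.0

            # draining tree: sink toward the resolved outflow nodes
            if beta_outflow is not None and out_kd is not None:
                oidx = out_kd.query_ball_point(x, rho)
                if oidx:
                    oidx = np.asarray(oidx)
                    q_avg = out_flows[oidx].sum() / vol
                    p_node = float(out_p[oidx].mean())
                    p_outflow[c] = p_node
                    p1 = p_avg[1][c]
                    gap = abs(p1 - p_node) if not np.isnan(p1) else 0.0
                    beta_outflow[c] = abs(q_avg) / gap if gap > 0 else 0.0

        # permeability floor: isotropic addition on singular cells only
        fields = {}
        for i, Kc in K_cells.items():
            eigmax = np.linalg.eigvalsh(Kc).max() if len(Kc) else 0.0
            floor = config.floor_rel * eigmax
            eigmin = np.linalg.eigvalsh(Kc)[:, 0]
            flagged = eigmin < floor
            Kc[flagged] += floor * np.eye(2)
            fields[i] = PermeabilityField(
                K=Kc, floored=flagged, configuration="current", floor_value=floor
            )
        perm.append(fields)
        coupling.append(
            PerfusionCoupling(
                beta_terminal=beta_term,
                p_out_terminal=p_out_term,
                beta_internal=beta_internal,
                beta_outflow=beta_outflow,
                p_outflow=p_outflow,
            )
        )
        if tree.role == "supplying":
            sources.append(SourceField(out_pos, out_flows, config.sigma, dim=2))
        else:
            sources.append(None)
    return perm, coupling, sources
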