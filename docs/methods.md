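# Methods

This note records the mathematical formulation and the numerical
choices behind each module. Units are kg–mm–s throughout: pressure in
kPa, flow in mm³/s, permeability in mm³·s/kg, power in µW; blood
viscosity defaults to η = 3.6·10⁻⁶ kPa·s.

## 1. Vessel trees (`tree`, `synthesis`)

A tree is a rooted binary network of straight segments. Segment *a*
with radius `r_a`, length `ℓ_a` and viscosity `η` has Poiseuille
resistance

    ζ_a = 8 η ℓ_a / (π r_a⁴),

so the pressure drop is `δp_a = ζ_a Q_a`. Terminal segments carry
equal flows `Q_term = q_perf / N_term`; internal flows follow from
Kirchhoff balance at the junctions and are computed exactly by one
leaf-to-root accumulation (`compute_flows`; residuals are at machine
precision by construction).

The total metabolic cost is viscous dissipation plus a maintenance
term proportional to blood volume,

    P = Σ_a ζ_a Q_a² + m_b Σ_a π r_a² ℓ_a .

Minimizing over radii segment-by-segment gives the power-optimal law

    r_a = (16 η / (m_b π²))^{1/6} Q_a^{1/3}     (`optimal_radii`),

at which the viscous and volumetric parts are equal (`P_vis = P/2`)
and the cost reduces to the topology-only surrogate

    P = k Σ_a Q_a^{2/3} ℓ_a ,   k = 1.5 m_b π c²,   c = (16η/(m_bπ²))^{1/6},

since `r_a² = c² Q_a^{2/3}` makes `P_vol = m_b π c² Σ Q^{2/3} ℓ` and
`P = P_vis + P_vol = 1.5 P_vol` at the optimum.

Synthesis proceeds in three stages:

1. **Terminal sampling** — uniform rejection sampling in the domain
   (`DomainSpec.disk` / `rectangle`) with an optional clearance from
   the boundary.
2. **Initial topology** — greedy agglomeration: repeatedly join the
   two closest open subtrees (recursive bisection for very large
   trees), then attach to the root.
3. **Simulated-annealing parent swaps** — a move detaches node *u*
   and re-attaches it under node *v*; the cost change `df` is updated
   incrementally (verified exact against recomputation to 1e-14).
   Proposals are locality-biased (80 % drawn from the 12 spatial
   nearest neighbours of *u*), because uniform pairs almost never
   improve a good agglomerative start. The initial temperature is the
   median |df| over *improving* candidate moves — the raw spread of
   all candidates is dominated by strongly uphill proposals and would
   keep the walk in the random regime for the whole schedule. The
   temperature is cooled geometrically (factor 0.9 per batch), a
   greedy phase then accepts only improving swaps until a full batch
   finds none, and the best topology ever seen is returned.
4. **Geometric relaxation** — interior branching nodes minimize
   `Σ w_a ℓ_a` with weights `w_a = k Q_a^{2/3}` frozen at the current
   flows; each node solves a weighted Fermat problem by blockwise
   Weiszfeld iteration (monotone non-increasing objective). Moves
   that would shorten any incident segment below `l_min` are
   reverted. Flows and radii are recomputed afterwards.

A supplying/draining pair with shared terminals forms a
`VascularForest`; `detect_intersections` reports segment crossings
between trees.

## 2. Compartment splitting (`compartments`)

Given strictly decreasing radius thresholds `r_0 > r_1 > … > r_{N-1}`
(a lone threshold `[t]` is normalized to `[t, 0]`), segment *a* is
assigned to the resolved hierarchy if `r_a > r_0` and otherwise to
homogenized compartment `i` if `r_{i-1} ≥ r_a > r_i`. Every terminal
segment must land in the lowest compartment; violations raise an
error rather than being silently clipped. Interfaces between
consecutive compartments and the resolved→compartment outlets are
identified by shared proximal nodes together with the net flow they
carry; these feed the source and exchange estimators below.

## 3. RVE homogenization (`rve`, `population`)

Each mesh cell carries one circular representative volume element
(RVE) centred at the cell centroid. Every network segment is clipped
to the RVE (exact line–circle intersection); a clipped piece of
length `δℓ`, radius `r` and unit orientation `e` contributes to the
permeability tensor

    K = π / (8 |V|) Σ r⁴ δℓ / η  (e ⊗ e),

whose trace for N identical segments is the closed form
`N π R⁴ δL / (8 η |V|)` (used as a machine-precision oracle in the
tests). A single straight vessel gives a rank-1 tensor; rank-deficient
cells are regularized by adding `floor_rel × λ_max` isotropically and
flagged; empty cells get `K = floor·I` exactly. Cells with no overlap
with the perfusion domain are skipped.

Compartment pressures are averaged with vessel-volume weights, using
the midpoint pressure of each clipped piece under the linear
Poiseuille drop. The inter-compartment exchange (perfusion)
coefficient is

    β_{ik} = ⟨q⟩ / |⟨p⟩*_i − ⟨p⟩*_k| ,

with `⟨q⟩` the interface flow density in the RVE; β = 0 for empty
interfaces or zero pressure gap. Resolved-tree outlets into the
highest compartment are spread as isotropic Gaussian source densities

    θ(x) = Σ_u Q̂_u (2πσ²)^{-d/2} exp(−‖x − x_u‖² / 2σ²),

which integrate to the outlet flows exactly. The microcirculation is
an isotropic continuum with `K_micro = k_micro / η`; the intrinsic
permeability is either given (default 2·10⁻⁸ mm²) or derived from the
Kozeny–Carman relation `k = d² φ³ / (1 − φ²)`.

`population` generates large synthetic segment populations (default
100,000 segments, R = δL = 0.01 mm, η = 10⁻⁶ kPa·s, unit volume) with
orientations uniform on a given angular range; these drive the
update-strategy benchmarks and the statistical convergence tests.

## 4. Multi-compartment Darcy FEM (`mesh`, `fem`)

Each compartment *i* obeys Darcy flow with exchange and sink terms:

    −∇·(K_i ∇p_i) + Σ_k β_{ik} (p_i − p_k) + β_i^out (p_i − p_i^out) = θ_i

on a common triangulated domain with natural (zero-flux) boundary
conditions. Discretization uses P1 or P2 Lagrange triangles with
Dunavant quadrature (orders 2/4/6, verified against the exact
monomial integrals `∫ ξ^a η^b = a! b! /(a+b+2)!`). Permeability,
exchange and sink coefficients are cellwise constant; sources are
evaluated at quadrature points (a warning is issued when the Gaussian
spread σ falls below the mesh size).

Without sinks the operator has the constant vector in its nullspace.
Gauge handling: connected components of the compartment-coupling
graph are detected by union–find; components containing at least one
sink term are anchored and need no gauge, the rest either raise an
error (`gauge="fail"`) or receive a zero-mean Lagrange multiplier
(`gauge="zero-mean"`). The assembled system is symmetric; the energy
functional is evaluated at the zero-mean representative so that
constant modes contribute exactly zero instead of round-off noise.

Verification: the method of manufactured solutions with
`p* = cos(πx)cos(πy)` (source `θ = 2π² K p*`) converges at order
p + 1 in L² (measured rates ≈ 1.99 / 2.98 for P1 / P2); global mass
balance `∫θ − Σ sink outflow` closes to ~1e-14 of the inflow; a pure
sink equilibrium returns the uniform sink pressure exactly.

## 5. Deformation updates (`deform`)

Under a deformation gradient `F` (Jacobian `J = det F`), permeability
transforms between configurations as

    pull-back   K₀ = J F⁻¹ K F⁻ᵀ,      push-forward   K = J⁻¹ F K₀ Fᵀ,

and scalar densities (sources, exchange coefficients) scale with `J`.
A segment with reference orientation `Λ` stretches by
`ε = ‖FΛ‖²`; its radius updates by one of two laws:

* **constant resistance**: `r = ε^{1/4} R` — keeps `r⁴/ℓ` invariant,
  making the analytical closed form `K = J⁻¹ F K₀ Fᵀ` *exact*;
* **uniform porosity**: `r = (J φ_ratio / ε)^{1/2} R` with the
  porosity ratio `φ_ratio = Σ R² ε^{3/2} δL / (J Σ R² δL)` — keeps
  the vascular volume fraction spatially uniform.

Update strategies, in decreasing cost:

1. **re-homogenization** — deform every segment and re-average
   (reference; available under both radius laws);
2. **spectral update** — write `K₀ = Σ_n λ_n Λ_n ⊗ Λ_n` and update
   `K = J⁻¹ φ_ratio² F [Σ_n λ_n ε_n⁻³ … ] Fᵀ` from the
   eigendecomposition alone; exact for rigid rotations and isotropic
   stretches, approximate otherwise;
3. **binned spectral update** — partition segment orientations into
   `n_θ` bins (default 10) spanning the *occupied* orientation range
   `[φ_min, φ_max]` rather than the full `[0, π)`: for strongly
   anisotropic populations, fixed full-range bins would leave most
   bins empty and waste angular resolution, degrading the isochoric
   accuracy by an order of magnitude. One tensor per bin is updated
   spectrally and the results are summed. Tracks the
   uniform-porosity reference to ≲0.2 % (strongly anisotropic) and
   ≲0.1 % in the diagonal components (near-isotropic) at ~100× lower
   cost than re-homogenization;
4. **analytical update** — `K = J⁻¹ F K₀ Fᵀ`; matches
   constant-resistance re-homogenization to 1e-10 and costs one 2×2
   product.

Exchange coefficients update as `β₀ = J β` (`beta_update`);
`lagrangian_transform` applies the appropriate rule to whole cellwise
fields.

## 6. Benchmarks (`benchmark`)

* `run_update_benchmark` compares all five strategies on a segment
  population under rotation (π/4), isochoric stretch
  `diag(α⁻¹, α)` and isotropic scaling `α·I`, reporting tensors,
  per-component deviations from the matching re-homogenization
  reference and timings.
* `disk_benchmark` runs the full pipeline on a disk: a supplying and
  a draining tree (opposite roots, equal flow), radius-threshold
  splitting, RVE homogenization, and a three-compartment solve
  (supply → microcirculation → drain). Physical checks: supplied and
  drained flows balance, mean pressures order as
  supply > micro > drain, and the microcirculatory Darcy velocities
  sit orders of magnitude below the tree compartments.

Default study scales are reduced where full-size runs would not add
information: trees of a few hundred terminals (structure invariants
are scale-free and separately checked at the 21,991-terminal /
43,981-segment scale), RVE populations of 100,000 segments (enough
for ≲0.5 % statistical error in single components).
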