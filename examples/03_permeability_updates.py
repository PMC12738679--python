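"""Compare permeability-update strategies under prescribed deformation.

A population of 100,000 straight segments (R = dL = 0.01, eta = 1e-6)
inside a unit-square averaging volume is deformed by three modes —
rotation by pi/4, isochoric stretch diag(3/2, 2/3) and isotropic
shrinkage (2/3) I — and the homogenized tensor is updated five ways:

* re-homogenization, uniform-porosity radius law (accuracy oracle);
* re-homogenization, constant-resistance radius law r = eps^(1/4) R;
* global spectral update (single eigendecomposition);
* binned spectral update (10 orientation bins over the occupied range);
* analytical closed form K = J^-1 F K0 F^T (exact under constant
  resistance).

Scenario 1 uses strongly anisotropic orientations (uniform on
[pi/6, pi/3]); Scenario 2 near-isotropic ones (uniform on [0, pi]).
The binned spectral update tracks the uniform-porosity oracle to
~0.2 % while touching only 10 eigen-systems instead of 100,000
segments.

Run:  python examples/03_permeability_updates.py
"""

import numpy as np

from perfusim import RvePopulationSpec, generate_rve_population, run_update_benchmark

SCENARIOS = {
    "Scenario 1  (phi in [pi/6, pi/3], anisotropic)": (np.pi / 6, np.pi / 3),
    "Scenario 2  (phi in [0, pi], near-isotropic)": (0.0, np.pi),
}


def main():
    for title, phi_range in SCENARIOS.items():
        pop = generate_rve_population(
            RvePopulationSpec(n=100_000, phi_range=phi_range, seed=2024)
        )
        report = run_update_benchmark(pop, n_theta=10)
        print(f"\n=== {title} ===")
        print(report.to_table())

        # normalize by the oracle's largest component so a near-zero
        # off-diagonal entry does not inflate the relative deviation
        row = report.row("isochoric", "spectral-binned")
        ref = report.row("isochoric", "rehomog-uniform")
        scale = max(abs(ref[c]) for c in ("K_xx", "K_xy", "K_yy"))
        dev = max(abs(row[c] - ref[c]) for c in ("K_xx", "K_xy", "K_yy")) / scale
        print(
            "binned spectral vs uniform-porosity oracle (isochoric): "
            f"max scale-normalized deviation {100 * dev:.3f} %"
        )


if __name__ == "__main__":
    main()
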