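"""Bulk-solvent models and overall scaling.

Builds a flat solvent mask (probe + shrink + periodic cavity removal),
computes its Fourier coefficients, composes total structure factors, and
recovers known scale parameters by Gauss-Newton with eigenvalue filtering.
"""

import numpy as np

from xtalrefine import (
    SimulationSpec,
    babinet_factor,
    build_solvent_mask,
    direct_structure_factors,
    estimate_scales,
    make_toy_structure,
    mask_structure_factors,
    simulate_observations,
)

spec = SimulationSpec(n_residues=14, d_min=2.2, cell_padding=9.0, seed=3)
st = make_toy_structure(spec)
data = simulate_observations(st, spec)

mask = build_solvent_mask(st, grid_spacing=spec.d_min / 4.0)
f_mask = mask_structure_factors(mask, data.hkl)
print(f"solvent fraction {mask.solvent_fraction:.2f} on a {mask.grid.shape} grid")
print(f"F_mask(low-resolution) dominates: |F_mask| at d={data.d.max():.1f} A is "
      f"{np.abs(f_mask[np.argmax(data.d)]):.0f}, at d={data.d.min():.1f} A only "
      f"{np.abs(f_mask[np.argmin(data.d)]):.0f}")

# recover a known overall scale + isotropic B
fp = direct_structure_factors(st, data.hkl)
data.f_obs = 0.7 * np.abs(fp) * np.exp(-12.0 * data.s2 / 4.0)
sc = estimate_scales(data, fp)
print(f"\nrecovered k_overall = {sc.k_overall:.4f} (truth 0.7), "
      f"B_iso = {np.trace(sc.u_aniso) / 3 * 8 * np.pi**2:.3f} A^2 (truth 12)")

# recover Babinet solvent parameters
data.f_obs = np.abs(fp) * babinet_factor(np.sqrt(data.s2), 0.35, 150.0)
sc = estimate_scales(data, fp, use_babinet=True, use_aniso=False)
print(f"recovered Babinet k0 = {sc.k_babinet0:.4f} (truth 0.35), "
      f"B = {sc.b_babinet:.1f} A^2 (truth 150)")
print("\nthe Babinet pair is strongly correlated with the overall scale; the")
print("eigenvalue-filtered Gauss-Newton fit with a coarse grid start still")
print("pins all three to better than 1% on noise-free data.")
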