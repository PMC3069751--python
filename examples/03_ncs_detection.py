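"""Automatic NCS detection and global/local restraints.

Builds two copies of a 20-residue chain related by a rotation plus
translation, detects the relationship by sequence alignment and Procrustes
superposition, and evaluates the global and robust local NCS residuals.
"""

import numpy as np

from xtalrefine import (
    GMParams,
    SimulationSpec,
    detect_ncs,
    global_ncs_residual,
    local_ncs_residual,
    make_toy_structure,
)

st = make_toy_structure(SimulationSpec(n_residues=20, ncs_copy=True, seed=4,
                                       ncs_translation=(15.0, 4.0, 2.0)))
pairs = detect_ncs(st, prepare_local=True)
p = pairs[0]
print(f"chains {p.chain_a}/{p.chain_b}: {len(p.residue_pairs)} aligned residues,")
print(f"identity {p.identity:.0f}%, global rmsd {p.rmsd:.2e} A, "
      f"local rmsd {p.local_rmsd_value:.2e} A")

# perfectly superposed copies: both residuals are zero
xyz = st.positions()
v_g, _, _ = global_ncs_residual(pairs, xyz, weight=1.0)
v_l, _, _ = local_ncs_residual(pairs, xyz, GMParams(0.5), 1.0)
print(f"global NCS residual {v_g:.2e}, local NCS residual {v_l:.2e}")

# bend half of chain B: the robust local term saturates instead of exploding
idx_b = [i for i in st.chain_atoms("B") if st.atoms[i].resnum > 10]
xyz2 = xyz.copy()
xyz2[idx_b] += np.array([3.0, -2.0, 1.0])
v_g2, _, _ = global_ncs_residual(pairs, xyz2, weight=1.0)
v_l2, _, _ = local_ncs_residual(pairs, xyz2, GMParams(0.5), 1.0)
n_pairs = len(p.distance_pairs)
print(f"\nafter a 3.7 A hinge displacement of half of chain B:")
print(f"global NCS residual {v_g2:.1f} (quadratic: pulls hard)")
print(f"local NCS residual {v_l2:.1f} <= bound {n_pairs / 0.5**2:.0f}")
print("the Geman-McClure loss caps each distance pair at 1/sigma_GM^2, so a")
print("genuine conformational difference is tolerated rather than crushed.")
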