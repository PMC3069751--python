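# xtalrefine

Desk-scale maximum-likelihood refinement of macromolecular crystal
structures, for people who want to see the entire reciprocal-space
refinement stack — likelihood targets, bulk-solvent scaling, restraint
engineering and the Gauss–Newton machinery — as readable, testable Python
on synthetic toy crystals.

In crystallographic refinement an atomic model (positions **x**, atomic
displacement parameters B or **U**, occupancies, overall scales, twin
fractions) is adjusted to minimize

    f_total = f_geom + w · f_xray ,

where `f_xray` is a minus log-likelihood of the diffraction data and
`f_geom` restrains the model to sensible chemistry. The X-ray targets
implemented here are:

* **Rice** — the amplitude likelihood: acentric
  `P(|Fo|) = (2|Fo|/Σ) exp(−(|Fo|² + D²|Fc|²)/Σ) I₀(2D|Fo||Fc|/Σ)` and the
  centric `cosh` analogue, with the Luzzati error model
  `Σ = ε·Σ_mod(bin) + σ_o²`, D and Σ_mod estimated per resolution bin
  (working reflections → D, free reflections → Σ_mod);
* **MLHL** — Rice with an experimental phase prior encoded as
  Hendrickson–Lattman coefficients (A, B, C, D), integrated over the
  unknown phase by periodic trapezoid quadrature;
* **SAD** — the joint likelihood of Friedel mates (F⁺, F⁻) under a 2×2
  complex Gaussian with correlated protein-part errors, integrated over
  both unknown phases;
* **twin** — the likelihood of twinned intensities
  `I_obs ≈ Σ_d α_d |F(op_d h)|²` with per-reflection Rice priors,
  evaluated by the Laplace approximation; twin laws are screened by
  R_merge and an H-statistic fraction estimate, and fractions α_d are
  re-fit every cycle.

Around the targets sit the restraint families (covalent geometry from a
minimal dictionary, automatic global/local NCS with a Geman–McClure robust
loss, external distance restraints, Hessian-only "jelly-body" regularization
and Kullback–Leibler / rigid-bond / sphericity ADP restraints), bulk-solvent
models (Babinet and flat mask), rigid-body and TLS parameterizations, and a
Gauss–Newton optimizer with diagonally preconditioned conjugate gradients,
ridge escalation and step-halving shift control. `docs/methods.md` gives the
full account.

Everything runs on synthetic toy crystals produced by the built-in
generator — no external data are needed.

## Worked example

```python
import numpy as np
from xtalrefine import (SimulationSpec, make_toy_structure,
                        simulate_observations, perturb_structure,
                        RefineConfig, TargetWeights, refine)

spec = SimulationSpec(n_residues=10, d_min=2.0, seed=7)
truth = make_toy_structure(spec)          # ideal-geometry polyalanine helix
data = simulate_observations(truth, spec) # noise-free amplitudes to 2.0 A
start = perturb_structure(truth, 0.3, seed=8)  # coordinates off by 0.3 A rmsd

cfg = RefineConfig(target="rice", n_cycles=8, weights=TargetWeights(mode="auto"))
refined, trajectory = refine(start, data, cfg)

for t in trajectory:
    print(f"cycle {t['cycle']}: R_work {t['r_work']:6.2f}%  "
          f"R_free {t['r_free']:6.2f}%  bond rmsd {t['bond_rmsd']:.4f} A")
d = refined.positions() - truth.positions()
print("final coordinate rmsd: %.3f A" % np.sqrt((d**2).sum(1).mean()))
```

prints (abridged):

```
cycle 0: R_work  18.44%  R_free  20.90%  bond rmsd 0.0698 A
cycle 3: R_work   4.32%  R_free   5.36%  bond rmsd 0.0415 A
cycle 7: R_work   1.88%  R_free   2.27%  bond rmsd 0.0317 A
final coordinate rmsd: 0.061 A
```

R_work/R_free are the usual `Σ||Fo|−|Fc|| / Σ|Fo|` over working and
cross-validation reflections; the run starts 0.3 Å from the answer at
R ≈ 18% and converges into the truth. The `examples/` directory holds one
short narrative script per capability (refinement, twin screening and
refinement, NCS detection and restraints, solvent/scaling, MLHL phase
priors, TLS).

A thin command-line interface wraps the same calls:

```sh
xtalrefine simulate spec.json --out-prefix toy
xtalrefine refine toy.pdb toy.csv --n-cycles 10
xtalrefine ncs-detect toy.pdb
xtalrefine twin-check toy.pdb toy.csv
```

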