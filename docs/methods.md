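# Methods

`xtalrefine` is a desk-scale reciprocal-space refinement engine for
macromolecular crystallography. It adjusts an atomic model (coordinates,
atomic displacement parameters, overall scales, twin fractions) to maximize
the agreement with observed structure-factor amplitudes or intensities while
keeping the model chemically sensible through a ledger of restraints. This
note records the statistical model, the numerical choices, and what the
synthetic test bed does and does not demonstrate.

## Target function

The total target is

    f_total = f_geom + w * f_xray

where `f_xray` is a minus log-likelihood of the diffraction data and
`f_geom` collects the restraint families (covalent geometry, NCS, external
distances, ADP regularizers). The weight `w` is either user-supplied or, in
`auto` mode, chosen once at the first cycle so the X-ray and geometry
gradient norms match, then held fixed. The automatic choice is a pragmatic
stand-in (both components are log-probabilities, but "ideal geometry" is
hard to pin down statistically); the manual override exists because the
automatic weight can give unreasonably tight or loose geometry.

### Error model

Per reflection, the model structure factor is compared to the observation
through a complex (acentric) or real (centric) Gaussian with mean `D * F_c`
and variance

    Sigma = epsilon * Sigma_mod(bin) + sigma_o^2 ,

where `D` in [0, 1] is the Luzzati factor expressing coordinate error,
`Sigma_mod` the model variance, `epsilon` the point-group multiplicity
factor and `sigma_o` the experimental uncertainty. `D` and `Sigma_mod` are
estimated per resolution bin — `D` on working reflections, `Sigma_mod` on
free reflections, alternating bounded scalar maximizations until both move
by less than 1e-4 (at most 100 alternations) — and interpolated linearly in
1/d^2 between bin centres to avoid bin-edge jumps. Bins with fewer than 5
work or free reflections merge with their lower-resolution neighbour.

The joint estimation of (D, Sigma_mod) has an intrinsic soft ridge (raising
Sigma and lowering D both broaden the distribution); with ~10^3 reflections
per panel the per-bin Sigma_mod estimate carries ~4-5% sampling noise even
at high signal-to-noise. Recovery checks therefore measure the mean
absolute relative error across bins.

### Likelihood targets

* **Rice** (amplitudes): closed form with `I0`/`cosh` evaluated in log
  space via exponentially scaled Bessel functions, stable to arguments of
  1e6 and beyond. Analytic gradients with respect to `F_c`.
* **MLHL** (amplitudes + prior phases): the Hendrickson-Lattman prior
  `exp(A cos a + B sin a + C cos 2a + D sin 2a)` reweights the uniform
  phase measure, so a zero prior reduces *exactly* to the Rice value — this
  identity fixes the normalization convention. Acentric phase integrals use
  periodic trapezoid quadrature (spectrally accurate for smooth periodic
  integrands) starting at 180 nodes and doubling until the log-integral
  moves by less than 1e-8 (at most 4 doublings; failure to converge raises,
  signalling pathological HL magnitudes). Centric reflections use the exact
  two-point sum over the symmetry-allowed phases.
* **SAD** (Friedel pairs): the joint complex Gaussian of
  `(F+, conj(F-))` given `D * (Fc+, conj(Fc-))` with a 2x2 Hermitian
  covariance `[[S+, rho sqrt(S+ S-)], [rho sqrt(S+ S-), S-]]`. The
  correlation `rho` (default 0.9) expresses that the protein-part model
  error is common to both mates and only the anomalous part decouples them.
  The double phase integral uses a 64x64 periodic grid doubled until the
  value moves by less than 1e-7. Centric reflections fall back to the Rice
  target on the single amplitude (the mates are equivalent).
* **Twin** (intensities): the observation is Gaussian about
  `sum_d alpha_d |F(op_d h)|^2` with per-index Rice priors on the
  contributing asymmetric-unit amplitudes. The integral over the |F|
  variables is evaluated by the Laplace approximation at the mode, found by
  damped Newton iteration (tolerance 1e-10 on the scaled gradient, then a
  short Newton polish to machine precision — the log-determinant term of
  the Laplace value is first-order sensitive to the mode position). A
  bounded quasi-Newton rescue and, as a last resort, direct numeric
  quadrature guard against mode-search failure. Gradients combine the exact
  envelope term with the log-determinant correction assembled through the
  implicit-function theorem; the required third derivatives enter through
  finite differences of the analytic Hessian. Against direct quadrature the
  Laplace value is accurate to ~1e-4 relative at a few percent intensity
  noise, degrading to ~1e-3 for very broad intensity uncertainties.

Twin operators come from a curated catalogue of merohedral twin laws per
supported point group (tetragonal 4, trigonal 3, hexagonal 6, rhombohedral
3). Candidates are screened by R_merge (ceiling 0.5) and an initial
twin-fraction estimate from the H statistic, `alpha = (1 - 2<H>)/2` with
`H = |I1 - I2|/(I1 + I2)` over acentric cross pairs (reflections fixed by
the operator carry no twin signal and are excluded from the H test);
fractions below the 0.05 floor are dropped and the surviving set is closed
under composition with the point group. Fractions are re-fit every cycle by
intensity least squares with a simplex projection.

## Structure factors and scaling

`F_protein` is computed by direct summation over symmetry operators and
atoms with 4-Gaussian + constant form factors (International Tables 1992
coefficients for H, C, N, O, S, P, Se, Fe, Hg) and isotropic or anisotropic
Debye-Waller factors. At toy scale (a few hundred atoms, a few thousand
reflections) direct summation is exact and removes grid-interpolation error
from every derivative test; all derivatives with respect to positions,
B/U values and occupancies are analytic.

Two bulk-solvent models can be active simultaneously:

* **Babinet**: multiplicative `1 - k_babinet0 exp(-B_babinet |s|^2/4)`;
  parameter pairs that would drive the multiplier negative at an observed
  resolution are rejected during scaling.
* **Mask**: a flat solvent region built on a cell-commensurate grid
  (spacing d_min/4, probe 1.0 A, shrink 1.1 A). Protein is everything
  within (vdW + probe) of a symmetry-expanded atom; the solvent is then
  grown back by the shrink radius via periodic FFT dilation, and interior
  cavities — solvent components not connected (6-neighbour, periodic) to
  the largest component — are reassigned to protein. `F_mask` is the FFT of
  the indicator, normalized so F(000) is the solvent fraction times the
  cell volume.

The total structure factor is

    F_total = k_overall * exp(-2 pi^2 s^T U_aniso s)
              * (1 - k_babinet0 exp(-B_babinet |s|^2/4))
              * (F_protein + k_mask exp(-B_mask |s|^2/4) F_mask).

Scales are fit to the working amplitudes by Gauss-Newton with eigenvalue
filtering (eigenvalues below 1e-6 of the largest are pseudo-inverted to
zero), with step halving so the residual never increases. `U_aniso` is
parameterized directly in the symmetry-invariant tensor subspace (Reynolds
projection of the canonical basis, orthonormalized by SVD), so crystal
symmetry holds exactly at every iterate. The strongly correlated Babinet
pair (k0, B) starts from the best point of a small coarse grid. Twin
scaling fits observed intensities to `sum_d alpha_d |F_total,d|^2` with the
fractions projected to the simplex after every step.

## Restraint ledger

* **Covalent geometry** (`sum w (b_m - b_i)^2`, `w = 1/sigma^2`): bonds,
  angles, chiral volumes (signed triple product), best-fit-plane deviations
  and selected torsions, built from a minimal plain-text dictionary (GLY,
  ALA, SER, CYS, HOH, a toy ligand, plus the peptide link; an import shim
  reads standard `_chem_comp_bond`/`_chem_comp_angle` mmCIF loops). Only
  the peptide omega and side-chain chi torsions are restrained by default.
  Torsion differences wrap to the period-aware minimal image. The ideal
  chiral volume (2.484996 A^3) is the exact volume implied by the
  dictionary's own ideal bonds and angles, so generated chains score a zero
  residual. Plane terms use the envelope property of the least-squares
  plane: the gradient is exact, and the Gauss-Newton block (per-atom normal
  rows) is an always-PSD approximation.
* **NCS**: chains are aligned with Needleman-Wunsch (match +1, mismatch -1,
  gap -2), accepted above 15 aligned residues, 80% identity and below
  2.5 A superposition rmsd (Kabsch/Procrustes, proper rotation enforced).
  Waters/ligands whose transformed images land within 1.0 A are adopted
  into the correspondence, re-run every cycle. Local rmsd averages
  5-residue sliding-window superpositions and coincides with the global
  rmsd when the window spans the alignment. Global NCS restrains
  `w ||R x_i + t - x_j||^2` with (R, t) re-estimated each cycle but frozen
  in the derivatives; local NCS restrains differences of corresponding
  intra-chain distances (cutoff 4.25 A, shared with the jelly-body
  universe) through the Geman-McClure estimator.
* **Geman-McClure**: `rho(r) = r^2/(1 + sigma_GM^2 r^2)` with slope
  `2r/(1 + sigma^2 r^2)^2` and the positive curvature proxy
  `2/(1 + sigma^2 r^2)^2`; the exact second derivative turns negative at
  large residuals, the proxy keeps every assembled block PSD and the search
  directions descending. Default sigma_GM: 0.5 for local NCS, 3.0 for
  external restraints (dimensionless residual units).
* **External restraints**: text rows
  `chain1 resnum1 atom1 chain2 resnum2 atom2 dist sigma`; rows beyond d_max
  (default 10 A) drop, duplicates combine by inverse variance (multiple
  reference structures), value `w_ext sum GM((d - d0)/sigma)`.
* **Jelly body**: same-chain atom pairs within 4.25 A restrained to their
  *current* distance — zero value and gradient by construction; only the
  Gauss-Newton blocks enter, damping the search direction. Restraining all
  distances reproduces rigid-body-like behaviour, so the term interpolates
  implicitly between individual-atom and rigid-body refinement.
* **ADP restraints**: symmetrized Kullback-Leibler divergence between the
  zero-mean Gaussians of two atoms, `1/2 tr(U1 U2^-1 + U2 U1^-1 - 2I)`
  (this fixed convention is 2x the textbook symmetrized KL; the isotropic
  form `(3/2)(u1/u2 + u2/u1 - 2)` follows exactly). Pairs within 4.25 A
  carry class weights (bonded 4 : angle 2 : other 1) with a `(3/d)^2` decay
  beyond 3 A for non-bonded pairs. Rigid-bond restraints apply the 1D
  analogue `1/2 (u1/u2 + u2/u1 - 2)` to the bond-projected U values of
  bonded/angle pairs — for isotropic pairs this equals the KL restraint up
  to the fixed 1D/3D trace factor of 3. Sphericity restrains the Frobenius
  deviation of U from its isotropic equivalent `tr(U)/3 * I`, weighted
  `1/(1 + n_other_restraints)` so poorly-restrained atoms are held more
  strongly. Curvature blocks for the normal equations use the quadratic KL
  metric at the pair midpoint (PSD by construction). Note: the square root
  of the symmetrized KL behaves as a metric on realistic, mildly
  anisotropic ADP pairs, but strongly anisotropic extremes can violate the
  triangle inequality by a few percent — the property is empirical, not a
  theorem.

## Parameterizations

* **Individual**: 3 coordinates (+ 1 isotropic B) per atom.
* **Rigid body**: 6 parameters per group — intrinsic z-y-z Euler angles and
  a translation about the group's centre of mass at cycle start. Atomic
  gradients and the diagonal X-ray curvature map through the chain rule; no
  inter-group Hessian terms are formed. Geometry Gauss-Newton blocks are
  projected through the full group Jacobians, so restraints invariant under
  rigid motion contribute exactly zero group curvature (folding only block
  diagonals would add large spurious stiffness). Per-group eigenvalue
  filtering removes unsupported motions (e.g. the rotation about a colinear
  group's axis, or the z-y-z gauge direction at beta = 0). In P1 the
  amplitudes are invariant under a joint translation of everything — that
  null mode is physical, and recovery is judged origin-free.
* **TLS**: per group, symmetric T (A^2) and L (rad^2) tensors plus a screw
  tensor S (A rad) with the trace gauge tr(S) = 0 built into the 8-element
  parameterization — 20 parameters; per-atom
  `U = T + A L A^T + A S + S^T A^T` with `A` the cross-product matrix of
  (r - origin). The map is linear, so the chain-rule Jacobian is assembled
  exactly from 20 unit responses. The default grouping is one group per
  chain, with waters within 3.5 A joining that chain's group. An isotropic
  residual B per atom adds `(B/8 pi^2) I`; summed and split conventions
  both round-trip.

## Optimizer

Normal equations `H p = -G` assemble the X-ray Fisher-diagonal (positive
per-reflection curvature proxies: `2 D^2/Sigma` acentric, `D^2/Sigma`
centric; intensity-scale analogues for the twin target) with full sparse
Gauss-Newton blocks from every geometry-family restraint. All blocks are
PSD by construction, so H is PSD. The solve is conjugate gradients on the
diagonally preconditioned system (unit diagonal after preconditioning) to
relative residual 1e-8 within N_maxiter = 1000 iterations; on
non-convergence a ridge gamma starts at 1e-4 (times the unit preconditioned
diagonal) and grows tenfold, with a hard error past 1e6 times the start.
Shifts are applied full-step first and halved (up to 10 times) until
f_total does not increase; isotropic B clamps at 0.1 A^2 and anisotropic U
eigenvalues floor at 1e-4 A^2. Each cycle re-estimates scales (and twin
fractions), the D/Sigma model and the NCS transformations before
reassembly; refinement runs a fixed cycle count (default 10). A divergence
guard aborts if R_work rises by more than 10 percentage points over 3
cycles.

## Synthetic test bed

The generator builds polyalanine chains on exactly ideal dictionary
geometry (natural-extension placement at helical torsions phi = -57,
psi = -47, omega = 180; carbonyl and peptide-plane placement is
internally consistent so the covalent residual is identically zero), or
randomly packed C/N/O atoms with a 1.8 A clash floor for non-chain tests.
Observations are direct-summation amplitudes with relative Gaussian noise
(noise on intensities in twin simulations, where intensities are the
observable), deterministic hash-based free flags (default 5%), optional
Friedel pairs with anomalous corrections, and unimodal von Mises HL
coefficients (`A = kappa cos(alpha_true)`, `B = kappa sin(alpha_true)`,
C = D = 0). Everything is a pure function of (spec, seed).

What passing tests show — and what they do not: the engine provably
minimizes its stated target, its derivatives are exact, and it recovers
known parameters from data generated by its own forward model at desk
scale. Real data add model incompleteness, correlated and non-Gaussian
errors, disordered solvent that the flat mask only approximates,
radiation damage, and crystal pathologies (pseudo-translation, modulation)
that this error model does not cover. Headline study conditions used by
the acceptance script: 30-residue / 150-atom P1 toy at 2.0 A (~19,000
reflections) for coordinate recovery; 60-atom P4(1) toy at 1.8 A with twin
fraction 0.30 and 3% intensity noise for twin recovery; four bins of 2000
work + 2000 free reflections for the error-model recovery. These sizes
were chosen as the smallest at which the statistical claims are
well-conditioned.

## Known limitations

* SIRAS is not implemented; SAD is the representative multivariate target.
* Twin-law discovery is catalogue-based, not a general cell/space-group
  search; pseudo-merohedral laws for special monoclinic/orthorhombic cells
  are not catalogued.
* The X-ray Hessian contribution is diagonal-only (Fisher diagonal); far
  from the solution the quadratic model is conservative and convergence is
  linear until the basin is reached.
* Occupancies are modelled in the structure-factor derivatives but not
  refined by the driver.
* The monomer dictionary is a minimal fixture set, not a general library;
  sigma values are declared conventions, not literature constants.
* Space-group support is the curated list P1, P2(1), C2, P2(1)2(1)2(1),
  P3(1), P4(1), P6(1), R3.
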