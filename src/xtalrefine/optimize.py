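"""Gauss-Newton refinement engine.

Assembles sparse normal equations H p = -G from the X-ray target (Fisher
diagonal) plus full sparse blocks from the geometry-family restraints
(covalent, NCS, external, jelly-body, ADP), solves them by diagonally
preconditioned conjugate gradients with ridge (gamma) escalation on
non-convergence, and applies shifts with step halving and ADP positivity
control.

Total target: f_total = f_geom + w * f_xray, with w either manual or chosen
automatically at the first cycle so the two gradient norms match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .adp import adp_restraint_term, build_adp_pairs
from .external import ExternalRestraint, external_residual, jelly_body_contribution
from .geometry import GeometryTerm, bond_rmsd, build_geometry_terms, geometry_residual
from .groups import RigidGroup, TLSGroup, rigid_body_apply, rigid_body_chain_rule, tls_chain_rule
from .likelihood import (
    CovarianceModel,
    estimate_d_sigma,
    rice_nll_terms,
    mlhl_nll,
    sad_nll,
    xray_curvature_weights,
)
from .model import Structure
from .ncs import GMParams, NCSPair, global_ncs_residual, local_ncs_residual, update_transformations
from .reflections import ReflectionSet, assign_resolution_bins, compute_r_factors
from .scattering import (
    ScaleModel,
    build_solvent_mask,
    direct_structure_factors,
    estimate_scales,
    estimate_scales_twin,
    mask_structure_factors,
    structure_factor_derivs,
    total_structure_factors,
)
from .twin import TwinModel, twin_nll

__all__ = [
    "NormalEquations",
    "TargetWeights",
    "RefineConfig",
    "RidgeEscalationError",
    "assemble_normal_equations",
    "pcg_solve",
    "ridge_escalation_solve",
    "apply_shifts",
    "refine",
]

log = logging.getLogger(__name__)

B_MIN = 0.1  # A^2, isotropic ADP floor after shifts
U_EIG_FLOOR = 1e-4  # A^2, anisotropic eigenvalue floor


class RidgeEscalationError(RuntimeError):
    """CG failed to converge even with the maximum ridge (pathological H)."""


@dataclass
class TargetWeights:
    """Relative weights of the target components."""

    w_xray: float = 1.0
    mode: str = "manual"  # manual | auto
    w_ncs_global: float = 0.0
    w_ncs_local: float = 0.0
    w_external: float = 0.0
    jelly_sigma: float = 0.0  # 0 disables jelly-body
    w_adp: float = 0.0
    sigma_gm: float = 3.0

    def __post_init__(self) -> None:
        for f in ("w_xray", "w_ncs_global", "w_ncs_local", "w_external", "w_adp"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass
class NormalEquations:
    """Sparse approximate Hessian + gradient: the optimizer's working state."""

    h: csr_matrix
    g: np.ndarray
    gamma: float = 0.0
    n_maxiter: int = 1000

    @property
    def n(self) -> int:
        return len(self.g)

    def precond_diag(self) -> np.ndarray:
        d = np.asarray(self.h.diagonal(), dtype=float)
        return np.where(d > 1e-300, d, 1.0)


def assemble_normal_equations(
    n_params: int,
    gradient: np.ndarray,
    blocks: list[tuple[np.ndarray, np.ndarray]],
    fisher_diag: np.ndarray | None = None,
    n_maxiter: int = 1000,
) -> NormalEquations:
    """Build sparse H from (param-index, dense block) pairs plus an optional
    diagonal (the X-ray Fisher contribution); G is the supplied gradient."""
    if len(gradient) != n_params:
        raise ValueError("gradient length does not match parameter count")
    rows, cols, vals = [], [], []
    if fisher_diag is not None:
        if len(fisher_diag) != n_params:
            raise ValueError("Fisher diagonal length mismatch")
        idx = np.arange(n_params)
        rows.append(idx)
        cols.append(idx)
        vals.append(np.asarray(fisher_diag, dtype=float))
    for pidx, blk in blocks:
        pidx = np.asarray(pidx, dtype=int)
        m = len(pidx)
        if blk.shape != (m, m):
            raise ValueError("block shape does not match its index list")
        r, c = np.meshgrid(pidx, pidx, indexing="ij")
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(blk.ravel())
    if rows:
        h = coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_params, n_params),
        ).tocsr()
    else:
        h = csr_matrix((n_params, n_params))
    h = (h + h.T) * 0.5  # exact symmetry
    return NormalEquations(h=h, g=np.asarray(gradient, dtype=float), n_maxiter=n_maxiter)


def pcg_solve(eqs: NormalEquations, rtol: float = 1e-8) -> tuple[np.ndarray, int]:
    """Solve (H + gamma I) p = -G by diagonally preconditioned CG.

    Raises RidgeEscalationError when CG does not converge within n_maxiter
    (the caller escalates gamma)."""
    d = eqs.precond_diag()
    dmh = 1.0 / np.sqrt(d)
    h = eqs.h

    def matvec(x):
        return dmh * (h @ (dmh * x)) + eqs.gamma * x

    op = LinearOperator((eqs.n, eqs.n), matvec=matvec)
    b = -(dmh * eqs.g)
    count = {"n": 0}

    def cb(_):
        count["n"] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        x, info = cg(op, b, rtol=rtol, atol=0.0, maxiter=eqs.n_maxiter, callback=cb)
    if info > 0:
        raise RidgeEscalationError(
            f"CG did not converge in {eqs.n_maxiter} iterations (needs ridge)"
        )
    if info < 0:  # pragma: no cover
        raise RuntimeError("CG failed with an illegal input")
    return dmh * x, count["n"]


def ridge_escalation_solve(eqs: NormalEquations) -> tuple[np.ndarray, float, int]:
    """gamma-escalation: start at gamma = 0; on CG non-convergence start from
    gamma0 = 1e-4 (the preconditioned matrix has unit diagonal) and multiply
    by 10; hard error beyond 1e6 * gamma0.

    Returns (shift, gamma used, CG iterations)."""
    gamma0 = 1e-4
    gamma = 0.0
    while True:
        eqs.gamma = gamma
        try:
            p, iters = pcg_solve(eqs)
            return p, gamma, iters
        except RidgeEscalationError:
            gamma = gamma0 if gamma == 0.0 else gamma * 10.0
            if gamma > 1e6 * gamma0:
                raise RidgeEscalationError(
                    "ridge escalation exhausted (pathological normal matrix)"
                )
            log.info("CG non-convergence: escalating ridge to gamma=%g", gamma)


# ---------------------------------------------------------------------------
# X-ray targets
# ---------------------------------------------------------------------------


@dataclass
class XrayState:
    """Per-cycle X-ray bookkeeping shared by the targets."""

    f_protein: np.ndarray
    f_mask: np.ndarray | None
    scale: ScaleModel
    cov: CovarianceModel
    f_total: np.ndarray
    prefactor: np.ndarray  # dF_total/dF_protein (complex per reflection)


def _xray_state(structure, rset, cov=None, use_mask=False, use_babinet=False,
                d_min=None, anomalous=None, n_bins=None, scale=None):
    sfd = structure_factor_derivs(structure, rset.hkl, anomalous=anomalous)
    f_mask = None
    if use_mask:
        dmin = d_min if d_min is not None else float(rset.d.min())
        mask = build_solvent_mask(structure, grid_spacing=dmin / 4.0, d_min=dmin)
        f_mask = mask_structure_factors(mask, rset.hkl)
    if scale is None:
        scale = estimate_scales(rset, sfd.f, f_mask=f_mask, use_babinet=use_babinet)
    f_total = total_structure_factors(sfd.f, f_mask, scale, rset.cell, rset.hkl)
    s_cart = rset.cell.recip_vectors(rset.hkl)
    s2 = np.einsum("ni,ni->n", s_cart, s_cart)
    from .scattering import babinet_factor

    pref = (
        scale.k_overall
        * scale.aniso_factor(s_cart)
        * babinet_factor(np.sqrt(s2), scale.k_babinet0, scale.b_babinet)
    ).astype(complex)
    if cov is None:
        if rset.bin_index is None:
            assign_resolution_bins(rset, n_bins or max(min(len(rset) // 500, 20), 1))
        cov = estimate_d_sigma(rset, np.abs(f_total))
    return sfd, XrayState(
        f_protein=sfd.f, f_mask=f_mask, scale=scale, cov=cov,
        f_total=f_total, prefactor=pref,
    )


def _rice_target(rset, state):
    """Work-reflection Rice value and complex dNLL/dF_total per reflection."""
    d, sig = state.cov.per_reflection(rset)
    amp = np.abs(state.f_total)
    vals, g_amp = rice_nll_terms(rset.f_obs, amp, d, sig, rset.centric)
    sel = rset.work
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(amp > 0, state.f_total / amp, 0.0)
    g_complex = np.where(sel, g_amp, 0.0) * unit  # dNLL/dA + i dNLL/dB
    return float(vals[sel].sum()), g_complex


def _mlhl_target(rset, state):
    if rset.hl is None:
        raise ValueError("MLHL target needs Hendrickson-Lattman coefficients")
    d, sig = state.cov.per_reflection(rset)
    phases = rset.restricted_phases()
    value = 0.0
    g_complex = np.zeros(len(rset), dtype=complex)
    for i in range(len(rset)):
        if not rset.work[i]:
            continue
        v, ga, gb = mlhl_nll(
            rset.f_obs[i], state.f_total[i], rset.hl[i], d[i], sig[i],
            centric=bool(rset.centric[i]),
            restricted_phase=None if np.isnan(phases[i]) else phases[i],
        )
        value += v
        g_complex[i] = ga + 1j * gb
    return value, g_complex


def _sad_target(rset, state, structure, anomalous, sad_rho, cov):
    """SAD target over Friedel pairs; returns the value, the complex
    gradient w.r.t. F_total(+) per reflection and the gradient arrays for
    the Friedel-mate structure factors (chained by the caller)."""
    if not rset.has_anomalous:
        raise ValueError("SAD target needs Friedel-pair columns")
    sfd_m = structure_factor_derivs(structure, -rset.hkl, anomalous=anomalous)
    f_minus = total_structure_factors(
        sfd_m.f, None, state.scale, rset.cell, -rset.hkl
    )
    d_arr, sig_arr = cov.per_reflection(rset)
    value = 0.0
    g_plus = np.zeros(len(rset), dtype=complex)
    g_minus = np.zeros(len(rset), dtype=complex)
    both = (
        rset.work
        & ~rset.centric
        & np.isfinite(rset.f_plus)
        & np.isfinite(rset.f_minus)
    )
    sig_mod = rset.epsilon * cov.sigma_mod_of(rset.s2)
    for i in np.flatnonzero(both):
        s1 = sig_mod[i] + rset.sig_plus[i] ** 2
        s2 = sig_mod[i] + rset.sig_minus[i] ** 2
        v, gp, gm = sad_nll(
            rset.f_plus[i], rset.f_minus[i], state.f_total[i], f_minus[i],
            d_arr[i], s1, s2, rho=sad_rho,
        )
        value += v
        g_plus[i] = gp[0] + 1j * gp[1]
        g_minus[i] = gm[0] + 1j * gm[1]
    # centric / single-mate reflections fall back to the Rice target
    rest = rset.work & ~both
    amp = np.abs(state.f_total)
    vals, g_amp = rice_nll_terms(
        rset.f_obs[rest], amp[rest], d_arr[rest], sig_arr[rest], rset.centric[rest]
    )
    value += float(vals.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(amp[rest] > 0, state.f_total[rest] / amp[rest], 0.0)
    g_plus[rest] += g_amp * unit
    return value, g_plus, g_minus, sfd_m


def _twin_target(rset, state, twin_model):
    """Twinned-intensity Laplace target; returns per-index complex gradient
    and intensity-scale curvature weights per contributing index."""
    d_arr, sig_arr = state.cov.per_reflection(rset)
    io, sig_io = (rset.i_obs, rset.sig_i) if rset.has_intensities else (
        rset.f_obs**2, 2.0 * rset.f_obs * rset.sig_f)
    groups = twin_model.groups(rset)
    value = 0.0
    g_complex = np.zeros(len(rset), dtype=complex)
    curv = np.zeros(len(rset))
    amp = np.abs(state.f_total)
    for i in range(len(rset)):
        if not rset.work[i]:
            continue
        idx, coeffs = groups[i]
        if len(idx) == 0:
            continue
        v, grads = twin_nll(
            float(io[i]),
            float(sig_io[i]),
            state.f_total[idx],
            d_arr[idx],
            sig_arr[idx],
            coeffs,
            centric=rset.centric[idx],
        )
        value += v
        for k, j in enumerate(idx):
            g_complex[j] += grads[k, 0] + 1j * grads[k, 1]
            # Gauss-Newton curvature of the intensity residual w.r.t. F_j,
            # broadened by the Rice prior variance
            denom = sig_io[i] ** 2 + 4.0 * coeffs[k] ** 2 * amp[j] ** 2 * sig_arr[j]
            curv[j] += (2.0 * coeffs[k] * amp[j]) ** 2 / max(denom, 1e-30)
    return value, g_complex, curv


def xray_value_and_grad(
    structure: Structure,
    rset: ReflectionSet,
    target: str = "rice",
    cov: CovarianceModel | None = None,
    use_mask: bool = False,
    use_babinet: bool = False,
    twin_model: TwinModel | None = None,
    anomalous: dict | None = None,
    value_only: bool = False,
    scale: ScaleModel | None = None,
    sad_rho: float = 0.9,
):
    """X-ray target value, per-atom gradients, Fisher diagonals and state.

    Returns dict with: value, grad_xyz (n,3), grad_b (n,), grad_u ((n,3,3) for
    anisotropic atoms), fisher_xyz (n,3), fisher_b (n,), fisher_u6 (n,6),
    state (XrayState), r_work, r_free.
    """
    sfd, state = _xray_state(
        structure, rset, cov=cov, use_mask=use_mask, use_babinet=use_babinet,
        anomalous=anomalous, scale=scale,
    )
    twin_curv = None
    sad_extra = None
    if target == "rice":
        value, g_complex = _rice_target(rset, state)
    elif target == "mlhl":
        value, g_complex = _mlhl_target(rset, state)
    elif target == "sad":
        value, g_complex, g_minus, sfd_m = _sad_target(
            rset, state, structure, anomalous, sad_rho, state.cov
        )
        sad_extra = (g_minus, sfd_m)
    elif target == "twin":
        if twin_model is None:
            raise ValueError("twin target needs a TwinModel")
        value, g_complex, twin_curv = _twin_target(rset, state, twin_model)
    else:
        raise ValueError(f"unknown X-ray target {target!r}")

    if rset.has_intensities and target == "twin" and twin_model is not None:
        amp2 = np.stack(
            [np.abs(total_structure_factors(
                direct_structure_factors(structure, img, anomalous=anomalous),
                None, state.scale, rset.cell, img)) ** 2
             for img in twin_model.domain_indices(rset.hkl)]
        )
        icalc = twin_model.fractions @ amp2
        r_work, r_free = compute_r_factors_intensity(rset, icalc)
    else:
        r_work, r_free = compute_r_factors(rset, np.abs(state.f_total))

    out = {
        "value": value, "state": state, "r_work": r_work, "r_free": r_free,
    }
    if value_only:
        return out

    # chain rule through F_total = prefactor * (F_protein + const)
    gf = np.conj(g_complex * state.prefactor)  # (n_refl,)
    out["grad_xyz"] = np.real(np.einsum("h,haj->aj", gf, sfd.d_xyz))
    out["grad_b"] = np.real(np.einsum("h,ha->a", gf, sfd.d_b))
    if sad_extra is not None:
        # add the Friedel-mate chain (prefactor is even in h)
        g_minus, sfd_m = sad_extra
        gfm = np.conj(g_minus * state.prefactor)
        out["grad_xyz"] += np.real(np.einsum("h,haj->aj", gfm, sfd_m.d_xyz))
        out["grad_b"] += np.real(np.einsum("h,ha->a", gfm, sfd_m.d_b))
    if sfd.d_u is not None:
        g6 = np.real(np.einsum("h,haj->aj", gf, sfd.d_u))  # (n_atoms, 6)
        gu = np.zeros((len(structure), 3, 3))
        gu[:, 0, 0], gu[:, 1, 1], gu[:, 2, 2] = g6[:, 0], g6[:, 1], g6[:, 2]
        # d_u columns already double the off-diagonal response
        gu[:, 0, 1] = gu[:, 1, 0] = 0.5 * g6[:, 3]
        gu[:, 0, 2] = gu[:, 2, 0] = 0.5 * g6[:, 4]
        gu[:, 1, 2] = gu[:, 2, 1] = 0.5 * g6[:, 5]
        out["grad_u"] = gu
        out["grad_u6"] = g6

    if twin_curv is not None:
        w = twin_curv  # already restricted to work observations
    else:
        w = xray_curvature_weights(rset, state.cov) * rset.work
    wp = w * np.abs(state.prefactor) ** 2
    out["fisher_xyz"] = np.einsum("h,haj->aj", wp, np.abs(sfd.d_xyz) ** 2)
    out["fisher_b"] = np.einsum("h,ha->a", wp, np.abs(sfd.d_b) ** 2)
    if sfd.d_u is not None:
        out["fisher_u6"] = np.einsum("h,haj->aj", wp, np.abs(sfd.d_u) ** 2)
    return out


def compute_r_factors_intensity(rset, icalc):
    """R factors on |F| scale from intensities (twin runs)."""
    fo = np.sqrt(np.clip(rset.i_obs if rset.has_intensities else rset.f_obs**2, 0, None))
    fc = np.sqrt(np.clip(icalc, 0.0, None))
    out = []
    for mask in (rset.work, rset.free):
        out.append(100.0 * np.abs(fo[mask] - fc[mask]).sum() / fo[mask].sum())
    return out[0], out[1]


# ---------------------------------------------------------------------------
# shifts
# ---------------------------------------------------------------------------


def apply_shifts(
    structure: Structure,
    shift: np.ndarray,
    param_map: "ParameterMap",
    f_total_fn,
    f_current: float,
    max_halvings: int = 10,
) -> tuple[Structure, float, float]:
    """Apply a shift vector with step-halving control.

    The full Gauss-Newton step is tried first; if f_total increases, the step
    is halved (up to ``max_halvings``).  Isotropic B values are clamped to
    >= 0.1 A^2 and anisotropic U tensors floored to positive-definite.
    Returns (accepted structure, accepted f_total, step scale used)."""
    scale = 1.0
    for _ in range(max_halvings + 1):
        trial = structure.copy()
        param_map.apply(trial, scale * shift)
        _sanitize_adps(trial)
        f_new = f_total_fn(trial)
        if f_new <= f_current + 1e-12 * max(abs(f_current), 1.0):
            return trial, f_new, scale
        scale *= 0.5
    log.warning("step halving exhausted; cycle ends with zero shift")
    return structure, f_current, 0.0


def _sanitize_adps(structure: Structure) -> None:
    for a in structure.atoms:
        if a.u_aniso is None:
            a.b_iso = max(a.b_iso, B_MIN)
        else:
            w, v = np.linalg.eigh(0.5 * (a.u_aniso + a.u_aniso.T))
            if w.min() < U_EIG_FLOOR:
                a.u_aniso = (v * np.maximum(w, U_EIG_FLOOR)) @ v.T


# ---------------------------------------------------------------------------
# parameter maps
# ---------------------------------------------------------------------------


class ParameterMap:
    """Maps a flat shift vector onto structure parameters."""

    n_params: int

    def apply(self, structure: Structure, shift: np.ndarray) -> None:
        raise NotImplementedError


class IndividualMap(ParameterMap):
    """xyz (3 per atom) + isotropic B (1 per atom)."""

    def __init__(self, structure: Structure, refine_b: bool = True):
        self.n_atoms = len(structure)
        self.refine_b = refine_b
        self.n_params = 3 * self.n_atoms + (self.n_atoms if refine_b else 0)

    def coord_index(self, atom: int) -> np.ndarray:
        return np.arange(3 * atom, 3 * atom + 3)

    def b_index(self, atom: int) -> int:
        return 3 * self.n_atoms + atom

    def apply(self, structure: Structure, shift: np.ndarray) -> None:
        xyz = structure.positions() + shift[: 3 * self.n_atoms].reshape(-1, 3)
        structure.set_positions(xyz)
        if self.refine_b:
            db = shift[3 * self.n_atoms :]
            for a, d in zip(structure.atoms, db):
                if a.u_aniso is None:
                    a.b_iso += d


class RigidMap(ParameterMap):
    """Six parameters per rigid group; coordinates only.

    Shifts are applied relative to the group parameters captured at
    construction, so repeated ``apply`` calls (step halving) do not
    accumulate."""

    def __init__(self, groups: list[RigidGroup]):
        self.groups = groups
        self.base = [g.parameters().copy() for g in groups]
        self.n_params = 6 * len(groups)

    def apply(self, structure: Structure, shift: np.ndarray) -> None:
        xyz = structure.positions()
        for k, g in enumerate(self.groups):
            g.set_parameters(self.base[k] + shift[6 * k : 6 * k + 6])
            xyz[g.atom_indices] = rigid_body_apply(g)
        structure.set_positions(xyz)


class TLSMap(ParameterMap):
    """Twenty parameters per TLS group; ADPs only (residual B fixed)."""

    def __init__(self, groups: list[TLSGroup], b_residual: np.ndarray):
        self.groups = groups
        self.base = [g.parameters().copy() for g in groups]
        self.b_residual = b_residual
        self.n_params = 20 * len(groups)

    def apply(self, structure: Structure, shift: np.ndarray) -> None:
        from .groups import combine_tls_residual, tls_to_adp

        xyz = structure.positions()
        for k, g in enumerate(self.groups):
            g.set_parameters(self.base[k] + shift[20 * k : 20 * k + 20])
            u = combine_tls_residual(
                tls_to_adp(g, xyz[g.atom_indices]), self.b_residual[g.atom_indices]
            )
            for m, i in enumerate(g.atom_indices):
                structure.atoms[i].u_aniso = u[m]


# ---------------------------------------------------------------------------
# refinement driver
# ---------------------------------------------------------------------------


@dataclass
class RefineConfig:
    target: str = "rice"  # rice | mlhl | twin
    parameterization: str = "individual"  # individual | rigid | tls
    n_cycles: int = 10
    weights: TargetWeights = field(default_factory=TargetWeights)
    refine_b: bool = True
    use_mask_solvent: bool = False
    use_babinet: bool = False
    n_bins: int | None = None
    ncs_pairs: list[NCSPair] = field(default_factory=list)
    external_restraints: list[ExternalRestraint] = field(default_factory=list)
    twin_model: TwinModel | None = None
    anomalous: dict | None = None
    dictionary: object | None = None
    n_maxiter: int = 1000
    max_halvings: int = 10
    divergence_window: int = 3
    divergence_rwork: float = 10.0  # percentage points


def _geometry_value(structure, terms, cfg, coords=None):
    """All geometry-family contributions to f_total (no jelly: value is 0)."""
    coords = structure.positions() if coords is None else coords
    total, _, _ = geometry_residual(terms, coords)
    w = cfg.weights
    gm = GMParams(w.sigma_gm)
    if cfg.ncs_pairs and w.w_ncs_global > 0:
        v, _, _ = global_ncs_residual(cfg.ncs_pairs, coords, w.w_ncs_global)
        total += v
    if cfg.ncs_pairs and w.w_ncs_local > 0:
        v, _, _ = local_ncs_residual(cfg.ncs_pairs, coords, gm, w.w_ncs_local)
        total += v
    if cfg.external_restraints and w.w_external > 0:
        v, _, _ = external_residual(cfg.external_restraints, coords, w.w_external, gm)
        total += v
    if w.w_adp > 0 and getattr(cfg, "_adp_pairs", None):
        v, _, _, _ = adp_restraint_term(cfg._adp_pairs, structure)
        total += v * w.w_adp
    return total


def refine(
    structure: Structure,
    rset: ReflectionSet,
    config: RefineConfig | None = None,
) -> tuple[Structure, list[dict]]:
    """Run Gauss-Newton refinement cycles.

    Per cycle: (1) scale/solvent (and twin-fraction) estimation, (2) D/Sigma
    estimation, (3) restraint rebuild (NCS transformations re-estimated),
    (4) normal-equation assembly, (5) PCG solve with ridge escalation,
    (6) shift application with halving.  Returns the refined structure and a
    per-cycle trajectory (f_total, R_work, R_free, bond rmsd, weight, gamma,
    CG iterations)."""
    cfg = config or RefineConfig()
    st = structure.copy()
    dictionary = cfg.dictionary
    if dictionary is None:
        from .dictionary import default_dictionary

        dictionary = default_dictionary()
    terms = build_geometry_terms(st, dictionary)
    if cfg.weights.w_adp > 0:
        cfg._adp_pairs = build_adp_pairs(st, terms)
    else:
        cfg._adp_pairs = None
    if rset.bin_index is None:
        assign_resolution_bins(rset, cfg.n_bins or max(min(len(rset) // 500, 20), 1))

    chain_of = np.array([a.chain for a in st.atoms])
    trajectory: list[dict] = []
    w_xray = cfg.weights.w_xray
    twin_model = cfg.twin_model

    for cycle in range(cfg.n_cycles):
        # (1)+(2) overall parameters, error model, X-ray derivatives
        if cfg.target == "twin" and twin_model is not None and twin_model.is_twinned:
            fp_domains = np.stack(
                [direct_structure_factors(st, img, anomalous=cfg.anomalous)
                 for img in twin_model.domain_indices(rset.hkl)]
            )
            _, fractions = estimate_scales_twin(rset, fp_domains, twin_model.fractions)
            twin_model = TwinModel(operators=twin_model.operators, fractions=fractions)
            cfg.twin_model = twin_model
        if cfg.ncs_pairs:
            update_transformations(st, cfg.ncs_pairs)  # step (vi) re-run per cycle

        xr = xray_value_and_grad(
            st, rset, target=cfg.target, use_mask=cfg.use_mask_solvent,
            use_babinet=cfg.use_babinet, twin_model=twin_model,
            anomalous=cfg.anomalous,
        )
        cov = xr["state"].cov
        coords = st.positions()
        geom_val, geom_grad, geom_blocks = geometry_residual(terms, coords)

        # automatic X-ray weight: match gradient norms at the first cycle
        if cycle == 0 and cfg.weights.mode == "auto":
            gx = np.linalg.norm(xr["grad_xyz"])
            gg = np.linalg.norm(geom_grad)
            if gx > 0:
                w_xray = gg / gx
            log.info("auto X-ray weight: %.4g", w_xray)

        # (3)+(4) assemble
        pmap, shift_eqs = _assemble_cycle(
            st, rset, cfg, xr, terms, geom_grad, geom_blocks, coords, chain_of,
            w_xray, cov,
        )

        # (5) solve
        try:
            shift, gamma, iters = ridge_escalation_solve(shift_eqs)
        except RidgeEscalationError:
            log.warning("cycle %d: normal equations unsolvable; stopping", cycle)
            break

        # (6) apply with halving
        def f_total_fn(trial):
            xe = xray_value_and_grad(
                trial, rset, target=cfg.target, use_mask=cfg.use_mask_solvent,
                use_babinet=cfg.use_babinet, twin_model=twin_model,
                anomalous=cfg.anomalous, cov=cov, value_only=True,
            )
            return _geometry_value(trial, terms, cfg) + w_xray * xe["value"]

        f_current = _geometry_value(st, terms, cfg) + w_xray * xr["value"]
        st, f_new, step_scale = apply_shifts(
            st, shift, pmap, f_total_fn, f_current, max_halvings=cfg.max_halvings
        )

        rms_bond = bond_rmsd(terms, st.positions())
        trajectory.append(
            {
                "cycle": cycle,
                "f_total": f_new,
                "r_work": xr["r_work"],
                "r_free": xr["r_free"],
                "bond_rmsd": rms_bond,
                "weight": w_xray,
                "gamma": gamma,
                "cg_iterations": iters,
                "step_scale": step_scale,
            }
        )
        if _diverging(trajectory, cfg):
            raise RuntimeError(
                "refinement diverging: R_work rose by more than "
                f"{cfg.divergence_rwork} points over {cfg.divergence_window} cycles"
            )
    return st, trajectory


def _group_jacobians(group: RigidGroup) -> dict[int, np.ndarray]:
    """Per-atom (3, 6) position Jacobians of a rigid group, keyed by atom."""
    from .groups import _rigid_jacobian

    jac = _rigid_jacobian(group)
    return {ai: jac[m] for m, ai in enumerate(group.atom_indices)}


def _diverging(trajectory, cfg):
    k = cfg.divergence_window
    if len(trajectory) <= k:
        return False
    return trajectory[-1]["r_work"] - trajectory[-1 - k]["r_work"] > cfg.divergence_rwork


def _assemble_cycle(st, rset, cfg, xr, terms, geom_grad, geom_blocks, coords,
                    chain_of, w_xray, cov):
    w = cfg.weights
    gm = GMParams(w.sigma_gm)
    n_atoms = len(st)

    if cfg.parameterization == "individual":
        pmap = IndividualMap(st, refine_b=cfg.refine_b)
        n_params = pmap.n_params
        grad = np.zeros(n_params)
        fisher = np.zeros(n_params)
        grad[: 3 * n_atoms] = (w_xray * xr["grad_xyz"] + geom_grad).ravel()
        fisher[: 3 * n_atoms] = (w_xray * xr["fisher_xyz"]).ravel()
        blocks = []

        def coord_block(atom_idx, blk):
            pidx = np.concatenate([pmap.coord_index(a) for a in atom_idx])
            blocks.append((pidx, blk))

        for idx, blk in geom_blocks:
            coord_block(idx, blk)
        if cfg.ncs_pairs and w.w_ncs_global > 0:
            v, g, bl = global_ncs_residual(cfg.ncs_pairs, coords, w.w_ncs_global)
            grad[: 3 * n_atoms] += g.ravel()
            for idx, blk in bl:
                coord_block(idx, blk)
        if cfg.ncs_pairs and w.w_ncs_local > 0:
            v, g, bl = local_ncs_residual(cfg.ncs_pairs, coords, gm, w.w_ncs_local)
            grad[: 3 * n_atoms] += g.ravel()
            for idx, blk in bl:
                coord_block(idx, blk)
        if cfg.external_restraints and w.w_external > 0:
            v, g, bl = external_residual(
                cfg.external_restraints, coords, w.w_external, gm
            )
            grad[: 3 * n_atoms] += g.ravel()
            for idx, blk in bl:
                coord_block(idx, blk)
        if w.jelly_sigma > 0:
            for idx, blk in jelly_body_contribution(
                coords, chain_of, sigma=w.jelly_sigma
            ):
                coord_block(idx, blk)  # H only: no value/gradient by construction
        if cfg.refine_b:
            grad[3 * n_atoms :] = w_xray * xr["grad_b"]
            fisher[3 * n_atoms :] = w_xray * xr["fisher_b"]
            if w.w_adp > 0 and cfg._adp_pairs:
                _, gb, _, bblocks = adp_restraint_term(cfg._adp_pairs, st)
                grad[3 * n_atoms :] += w.w_adp * gb
                for (i, j), blk in bblocks:
                    blocks.append(
                        (np.array([pmap.b_index(i), pmap.b_index(j)]), w.w_adp * blk)
                    )
        eqs = assemble_normal_equations(
            n_params, grad, blocks, fisher_diag=fisher, n_maxiter=cfg.n_maxiter
        )
        return pmap, eqs

    if cfg.parameterization == "rigid":
        groups = [
            RigidGroup.from_structure(st, idx)
            for idx in (st.rigid_groups or {"all": list(range(n_atoms))}).values()
        ]
        pmap = RigidMap(groups)
        atomic_grad = w_xray * xr["grad_xyz"] + geom_grad
        atomic_h = w_xray * xr["fisher_xyz"]
        grad, hessians, filters = rigid_body_chain_rule(atomic_grad, atomic_h, groups)
        # project full geometry GN blocks through the group Jacobians (terms
        # invariant under rigid motion then contribute exactly zero; only
        # inter-group links survive, and cross-group Hessian terms are
        # dropped by design)
        group_of = np.full(n_atoms, -1)
        for k, g in enumerate(groups):
            group_of[g.atom_indices] = k
        jacs = [_group_jacobians(g) for g in groups]
        for idx, blk in geom_blocks:
            for k in set(int(group_of[a]) for a in idx if group_of[a] >= 0):
                rows = [a for a, ai in enumerate(idx) if group_of[ai] == k]
                jg = np.vstack(
                    [jacs[k][ai] for ai in (idx[a] for a in rows)]
                )  # (3m, 6)
                sel = np.concatenate([np.arange(3 * a, 3 * a + 3) for a in rows])
                hessians[k] += jg.T @ blk[np.ix_(sel, sel)] @ jg
        blocks = []
        for k, (h, filt) in enumerate(zip(hessians, filters)):
            wv, vv = np.linalg.eigh(h)
            wv[filt] = wv.max() if wv.max() > 0 else 1.0  # filtered: no motion
            blocks.append((np.arange(6 * k, 6 * k + 6), (vv * wv) @ vv.T))
        eqs = assemble_normal_equations(
            pmap.n_params, grad, blocks, n_maxiter=cfg.n_maxiter
        )
        return pmap, eqs

    if cfg.parameterization == "tls":
        from .groups import default_tls_groups

        groups = (
            [TLSGroup.from_structure(st, idx) for idx in st.tls_groups.values()]
            if st.tls_groups
            else default_tls_groups(st)
        )
        b_res = st.b_values()
        pmap = TLSMap(groups, b_res)
        if "grad_u" not in xr:
            raise ValueError(
                "TLS refinement needs anisotropic atoms (apply the TLS map once first)"
            )
        grad = np.zeros(pmap.n_params)
        blocks = []
        xyz = st.positions()
        for k, g in enumerate(groups):
            gg, hh = tls_chain_rule(
                w_xray * xr["grad_u"][g.atom_indices],
                xyz[g.atom_indices],
                g,
                atomic_hess_u_diag=w_xray * xr["fisher_u6"][g.atom_indices],
            )
            grad[20 * k : 20 * k + 20] = gg
            blocks.append((np.arange(20 * k, 20 * k + 20), hh))
        eqs = assemble_normal_equations(
            pmap.n_params, grad, blocks, n_maxiter=cfg.n_maxiter
        )
        return pmap, eqs

    raise ValueError(f"unknown parameterization {cfg.parameterization!r}")
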