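"""Derived parameterizations: rigid-body groups (Euler angles + translation)
and TLS groups (Translation/Libration/Screw tensors), with chain-rule mapping
of atomic derivatives onto the group parameters.

Conventions: z-y-z intrinsic Euler angles; the rigid transform is
x_new = R (x_old - t_origin) + t_origin + t with t_origin the group's centre
of mass at cycle start.  TLS: U = T + A L A^T + A S + S^T A^T with A the
antisymmetric cross-product matrix of (r - origin); tr(S) = 0 fixes the
gauge, leaving 6 + 6 + 8 = 20 parameters per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import B_TO_U, Structure

__all__ = [
    "RigidGroup",
    "TLSGroup",
    "euler_zyz_matrix",
    "rigid_body_apply",
    "rigid_body_chain_rule",
    "tls_to_adp",
    "combine_tls_residual",
    "tls_chain_rule",
    "default_tls_groups",
]


def _rz(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _drz(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[-s, -c, 0.0], [c, -s, 0.0], [0.0, 0.0, 0.0]])


def _dry(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[-s, 0.0, c], [0.0, 0.0, 0.0], [-c, 0.0, -s]])


def euler_zyz_matrix(angles) -> np.ndarray:
    """Rotation matrix for intrinsic z-y-z Euler angles (radians)."""
    a, b, c = angles
    return _rz(a) @ _ry(b) @ _rz(c)


def _euler_zyz_derivs(angles) -> list[np.ndarray]:
    a, b, c = angles
    return [
        _drz(a) @ _ry(b) @ _rz(c),
        _rz(a) @ _dry(b) @ _rz(c),
        _rz(a) @ _ry(b) @ _drz(c),
    ]


@dataclass
class RigidGroup:
    """Six-parameter rigid group: Euler angles (radians) + translation (A)."""

    atom_indices: list[int]
    x_ref: np.ndarray  # (m, 3) reference coordinates at cycle start
    origin: np.ndarray  # centre of mass of x_ref
    euler: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @classmethod
    def from_structure(cls, structure: Structure, atom_indices) -> "RigidGroup":
        idx = list(atom_indices)
        x = structure.positions()[idx]
        return cls(atom_indices=idx, x_ref=x.copy(), origin=x.mean(axis=0))

    @property
    def n_params(self) -> int:
        return 6

    def parameters(self) -> np.ndarray:
        return np.concatenate([self.euler, self.translation])

    def set_parameters(self, p: np.ndarray) -> None:
        self.euler = np.asarray(p[:3], dtype=float).copy()
        self.translation = np.asarray(p[3:6], dtype=float).copy()


def rigid_body_apply(group: RigidGroup) -> np.ndarray:
    """x_new = R (x_ref - origin) + origin + t for the group's atoms."""
    r = euler_zyz_matrix(group.euler)
    return (group.x_ref - group.origin) @ r.T + group.origin + group.translation


def _rigid_jacobian(group: RigidGroup) -> np.ndarray:
    """(m, 3, 6) Jacobian of atom positions w.r.t. (euler, translation)."""
    m = len(group.atom_indices)
    jac = np.zeros((m, 3, 6))
    rel = group.x_ref - group.origin
    for k, dr in enumerate(_euler_zyz_derivs(group.euler)):
        jac[:, :, k] = rel @ dr.T
    jac[:, :, 3:] = np.broadcast_to(np.eye(3), (m, 3, 3))
    return jac


def rigid_body_chain_rule(
    atomic_grad: np.ndarray,
    atomic_hess_diag: np.ndarray,
    groups: list[RigidGroup],
    eig_filter: float = 1e-8,
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Map atomic (n, 3) gradients and (n, 3) diagonal curvatures onto the
    6-vector gradient and 6x6 Gauss-Newton Hessian per group.

    No inter-group Hessian terms are formed.  Each group Hessian is
    eigenvalue-filtered: directions with eigenvalues below
    ``eig_filter * max`` are reported for pseudo-inversion (degenerate group
    shapes, e.g. colinear groups, lose the unsupported rotations)."""
    grads, hessians, filters = [], [], []
    for g in groups:
        jac = _rigid_jacobian(g)  # (m, 3, 6)
        ga = atomic_grad[g.atom_indices]  # (m, 3)
        grads.append(np.einsum("maK,ma->K", jac, ga))
        ha = atomic_hess_diag[g.atom_indices]  # (m, 3)
        h = np.einsum("maK,ma,maL->KL", jac, ha, jac)
        w, _ = np.linalg.eigh(h)
        filters.append(w < eig_filter * max(w.max(), 1e-300))
        hessians.append(h)
    return np.concatenate(grads) if grads else np.zeros(0), hessians, filters


# ---------------------------------------------------------------------------
# TLS
# ---------------------------------------------------------------------------


def _skew(d: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -d[2], d[1]], [d[2], 0.0, -d[0]], [-d[1], d[0], 0.0]]
    )


@dataclass
class TLSGroup:
    """Translation/Libration/Screw tensors; 20 parameters per group."""

    atom_indices: list[int]
    origin: np.ndarray
    t_tensor: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    l_tensor: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    s_tensor: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    N_PARAMS = 20

    @classmethod
    def from_structure(cls, structure: Structure, atom_indices) -> "TLSGroup":
        idx = list(atom_indices)
        x = structure.positions()[idx]
        return cls(atom_indices=idx, origin=x.mean(axis=0))

    def __post_init__(self) -> None:
        self.t_tensor = 0.5 * (self.t_tensor + self.t_tensor.T)
        self.l_tensor = 0.5 * (self.l_tensor + self.l_tensor.T)
        # gauge: remove any trace from S
        self.s_tensor = self.s_tensor - (np.trace(self.s_tensor) / 3.0) * np.eye(3)

    def parameters(self) -> np.ndarray:
        """(T11,T22,T33,T12,T13,T23, L..., S11,S22,S12,S13,S21,S23,S31,S32)."""
        t, l_, s = self.t_tensor, self.l_tensor, self.s_tensor
        sym = lambda m: np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])
        s8 = np.array(
            [s[0, 0], s[1, 1], s[0, 1], s[0, 2], s[1, 0], s[1, 2], s[2, 0], s[2, 1]]
        )
        return np.concatenate([sym(t), sym(l_), s8])

    def set_parameters(self, p: np.ndarray) -> None:
        p = np.asarray(p, dtype=float)
        if len(p) != self.N_PARAMS:
            raise ValueError("TLS group takes exactly 20 parameters")

        def unsym(v):
            return np.array(
                [[v[0], v[3], v[4]], [v[3], v[1], v[5]], [v[4], v[5], v[2]]]
            )

        self.t_tensor = unsym(p[0:6])
        self.l_tensor = unsym(p[6:12])
        s11, s22, s12, s13, s21, s23, s31, s32 = p[12:20]
        self.s_tensor = np.array(
            [[s11, s12, s13], [s21, s22, s23], [s31, s32, -(s11 + s22)]]
        )


def tls_to_adp(group: TLSGroup, positions: np.ndarray) -> np.ndarray:
    """Per-atom anisotropic U from the TLS model:
    U = T + A L A^T + A S + S^T A^T, A = skew(r - origin).  Linear in
    (T, L, S); symmetric by construction."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    out = np.empty((len(positions), 3, 3))
    for k, r in enumerate(positions):
        a = _skew(r - group.origin)
        u = group.t_tensor + a @ group.l_tensor @ a.T + a @ group.s_tensor + group.s_tensor.T @ a.T
        out[k] = 0.5 * (u + u.T)
    return out


def combine_tls_residual(u_tls: np.ndarray, b_residual: np.ndarray) -> np.ndarray:
    """U_total = U_tls + (B_res / 8 pi^2) I per atom (TLSANL-style summed
    output; the split representation is recovered by subtraction)."""
    u_tls = np.asarray(u_tls, dtype=float)
    b_res = np.asarray(b_residual, dtype=float)
    if np.any(b_res < 0):
        raise ValueError("residual B must be non-negative")
    return u_tls + b_res[:, None, None] * B_TO_U * np.eye(3)


def _tls_u_jacobian(group: TLSGroup, positions: np.ndarray) -> np.ndarray:
    """(m, 6, 20) Jacobian of u6 = (U11,U22,U33,U12,U13,U23) w.r.t. the 20
    TLS parameters.  tls_to_adp is linear, so columns are exact unit
    responses."""
    m = len(positions)
    jac = np.empty((m, 6, 20))
    saved = group.parameters()
    try:
        for col in range(20):
            p = np.zeros(20)
            p[col] = 1.0
            group.set_parameters(p)
            u = tls_to_adp(group, positions)
            jac[:, :, col] = np.stack(
                [u[:, 0, 0], u[:, 1, 1], u[:, 2, 2], u[:, 0, 1], u[:, 0, 2], u[:, 1, 2]],
                axis=1,
            )
    finally:
        group.set_parameters(saved)
    return jac


def tls_chain_rule(
    atomic_grad_u: np.ndarray,
    positions: np.ndarray,
    group: TLSGroup,
    atomic_hess_u_diag: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Map per-atom dTarget/dU (matrix gradients, (m, 3, 3)) onto the
    20-vector TLS gradient (and optionally a 20x20 Gauss-Newton Hessian from
    per-atom diagonal U curvatures, (m, 6)).

    The S-trace gauge is built into the parameterization, so the projected
    gradient along the trace direction is exactly zero."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    gu = np.asarray(atomic_grad_u, dtype=float).reshape(-1, 3, 3)
    # 6-vector gradient with doubled off-diagonals (dU12 counts U12 and U21)
    g6 = np.stack(
        [
            gu[:, 0, 0],
            gu[:, 1, 1],
            gu[:, 2, 2],
            gu[:, 0, 1] + gu[:, 1, 0],
            gu[:, 0, 2] + gu[:, 2, 0],
            gu[:, 1, 2] + gu[:, 2, 1],
        ],
        axis=1,
    )
    jac = _tls_u_jacobian(group, positions)  # (m, 6, 20)
    grad = np.einsum("mup,mu->p", jac, g6)
    hess = None
    if atomic_hess_u_diag is not None:
        h6 = np.asarray(atomic_hess_u_diag, dtype=float).reshape(-1, 6)
        hess = np.einsum("mup,mu,muq->pq", jac, h6, jac)
    return grad, hess


def default_tls_groups(structure: Structure, water_shell: float = 3.5) -> list[TLSGroup]:
    """One TLS group per chain (the default), with waters within
    ``water_shell`` of a chain joining that chain's group (first hydration
    shell moves in concert with the protein)."""
    xyz = structure.positions()
    chain_atoms = {
        ch: [i for i in structure.chain_atoms(ch)
             if structure.atoms[i].resname.upper() != "HOH"]
        for ch in structure.chain_ids
    }
    chain_atoms = {ch: idx for ch, idx in chain_atoms.items() if idx}
    waters = [i for i, a in enumerate(structure.atoms) if a.resname.upper() == "HOH"]
    for w in waters:
        best, best_d = None, water_shell
        for ch, idx in chain_atoms.items():
            d = np.min(np.linalg.norm(xyz[idx] - xyz[w], axis=1))
            if d < best_d:
                best, best_d = ch, d
        if best is not None:
            chain_atoms[best].append(w)
    return [
        TLSGroup.from_structure(structure, sorted(idx))
        for ch, idx in chain_atoms.items()
    ]
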