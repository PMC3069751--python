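"""ADP restraint families: symmetrized Kullback-Leibler divergence between
atomic displacement distributions, Hirshfeld-style rigid-bond restraints on
bond-projected U values, and sphericity restraints on anisotropic tensors.

Conventions (fixed here, asserted by tests):
* 3D symmetric KL between zero-mean Gaussians with covariances U1, U2:
      KL = 1/2 tr(U1 U2^-1 + U2 U1^-1 - 2 I)
* 1D (bond-projection) version: 1/2 (u1/u2 + u2/u1 - 2); for isotropic pairs
  the rigid-bond restraint equals the KL restraint up to the fixed 1D/3D
  trace factor of 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import GeometryTerm
from .model import B_TO_U, Structure

__all__ = [
    "ADPPair",
    "kl_divergence_aniso",
    "kl_divergence_iso",
    "build_adp_pairs",
    "adp_restraint_term",
    "rigid_bond_term",
    "sphericity_term",
    "ADP_RMAX",
]

log = logging.getLogger(__name__)

ADP_RMAX = 4.25  # A, shared default with the jelly-body cutoff
DECAY_ONSET = 3.0  # A; weights decay as (3/d)^2 beyond this separation
WEIGHT_CLASSES = {"bonded": 4.0, "angle": 2.0, "other": 1.0}


@dataclass
class ADPPair:
    i: int
    j: int
    separation: float
    relation: str  # bonded | angle | other
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("ADP pair weight must be positive")


# ---------------------------------------------------------------------------
# divergences
# ---------------------------------------------------------------------------


def _check_pd(u: np.ndarray, what: str) -> None:
    if np.linalg.eigvalsh(u).min() <= 0:
        raise ValueError(f"{what} must be positive-definite")


def kl_divergence_aniso(u1: np.ndarray, u2: np.ndarray) -> float:
    """Symmetric KL between zero-mean Gaussians: 1/2 tr(U1 U2^-1 + U2 U1^-1 - 2I).

    Symmetric, rotation-equivariant, zero iff U1 = U2."""
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    _check_pd(u1, "U1")
    _check_pd(u2, "U2")
    a = np.linalg.solve(u2, u1)  # U2^-1 U1
    b = np.linalg.solve(u1, u2)
    return 0.5 * float(np.trace(a) + np.trace(b) - 6.0)


def kl_divergence_iso(b1: float, b2: float) -> float:
    """Isotropic case: (3/2)(u1/u2 + u2/u1 - 2) with u = B/(8 pi^2).

    Equals ``kl_divergence_aniso`` on the corresponding u*I tensors exactly;
    the value depends only on the ratio B1/B2."""
    if b1 <= 0 or b2 <= 0:
        raise ValueError("isotropic B must be positive")
    r = b1 / b2
    return 1.5 * (r + 1.0 / r - 2.0)


def _kl_iso_grad(b1: float, b2: float) -> tuple[float, float]:
    g1 = 1.5 * (1.0 / b2 - b2 / b1**2)
    g2 = 1.5 * (1.0 / b1 - b1 / b2**2)
    return g1, g2


def _kl_aniso_grad(u1: np.ndarray, u2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Matrix gradients of the symmetric KL w.r.t. U1 and U2."""
    i1 = np.linalg.inv(u1)
    i2 = np.linalg.inv(u2)
    g1 = 0.5 * (i2 - i1 @ u2 @ i1)
    g2 = 0.5 * (i1 - i2 @ u1 @ i2)
    return g1, g2


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------


def build_adp_pairs(
    structure: Structure,
    geometry_terms: list[GeometryTerm],
    r_max: float = ADP_RMAX,
    base_weight: float = 1.0,
) -> list[ADPPair]:
    """All atom pairs within ``r_max``; weights by relation class
    (bonded > angle > other) with a (3/d)^2 decay for non-bonded pairs beyond
    3 A."""
    bonded = set()
    angle_rel = set()
    for t in geometry_terms:
        if t.kind == "bond":
            bonded.add(tuple(sorted(t.atoms)))
        elif t.kind == "angle":
            angle_rel.add(tuple(sorted((t.atoms[0], t.atoms[2]))))
    angle_rel -= bonded

    from scipy.spatial import cKDTree

    xyz = structure.positions()
    tree = cKDTree(xyz)
    pairs = []
    for i, j in sorted(tree.query_pairs(r_max)):
        key = (i, j)
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if key in bonded:
            rel, w = "bonded", WEIGHT_CLASSES["bonded"]
        elif key in angle_rel:
            rel, w = "angle", WEIGHT_CLASSES["angle"]
        else:
            rel, w = "other", WEIGHT_CLASSES["other"]
            if d > DECAY_ONSET:
                w *= (DECAY_ONSET / d) ** 2
        pairs.append(ADPPair(i=int(i), j=int(j), separation=d, relation=rel,
                             weight=base_weight * w))
    return pairs


# ---------------------------------------------------------------------------
# restraint terms
# ---------------------------------------------------------------------------


def _u_of(structure: Structure, idx: int) -> np.ndarray:
    a = structure.atoms[idx]
    if a.u_aniso is not None:
        return a.u_aniso
    return a.b_iso * B_TO_U * np.eye(3)


def adp_restraint_term(
    pairs: list[ADPPair],
    structure: Structure,
) -> tuple[float, np.ndarray, dict[int, np.ndarray], list]:
    """sum w_ij KL(U_i, U_j) over ADP pairs (iso-iso, iso-aniso, aniso-aniso).

    Returns ``(value, grad_b, grad_u, blocks_b)``: the gradient w.r.t.
    isotropic B per atom, matrix gradients w.r.t. U for anisotropic atoms, and
    positive-semidefinite curvature blocks for the isotropic-B normal
    equations (quadratic KL metric at the pair midpoint)."""
    n = len(structure)
    value = 0.0
    grad_b = np.zeros(n)
    grad_u: dict[int, np.ndarray] = {}
    blocks_b: list[tuple[tuple[int, int], np.ndarray]] = []
    for p in pairs:
        ai, aj = structure.atoms[p.i], structure.atoms[p.j]
        iso_i, iso_j = ai.u_aniso is None, aj.u_aniso is None
        if iso_i and iso_j:
            b1, b2 = ai.b_iso, aj.b_iso
            value += p.weight * kl_divergence_iso(b1, b2)
            g1, g2 = _kl_iso_grad(b1, b2)
            grad_b[p.i] += p.weight * g1
            grad_b[p.j] += p.weight * g2
            # quadratic metric at the midpoint: KL ~ 3 (dB)^2 / (2 Bbar^2)
            bbar = 0.5 * (b1 + b2)
            m = 3.0 / bbar**2
            blk = p.weight * m * np.array([[1.0, -1.0], [-1.0, 1.0]])
            blocks_b.append(((p.i, p.j), blk))
        else:
            u1, u2 = _u_of(structure, p.i), _u_of(structure, p.j)
            value += p.weight * kl_divergence_aniso(u1, u2)
            g1, g2 = _kl_aniso_grad(u1, u2)
            for idx, g, iso in ((p.i, g1, iso_i), (p.j, g2, iso_j)):
                if iso:
                    # d/dB of KL(B/(8pi^2) I, .) = tr(g) * B_TO_U
                    grad_b[idx] += p.weight * float(np.trace(g)) * B_TO_U
                else:
                    grad_u[idx] = grad_u.get(idx, np.zeros((3, 3))) + p.weight * g
    return value, grad_b, grad_u, blocks_b


def rigid_bond_term(
    pairs: list[ADPPair],
    structure: Structure,
) -> tuple[float, np.ndarray, dict[int, np.ndarray]]:
    """Rigid-bond restraints on bonded/angle-related pairs: the projections
    u_k = n^T U_k n on the bond vector should match; contribution
    w * 1/2 (u1/u2 + u2/u1 - 2).  Only the bond-direction projection is
    restrained; perpendicular components are free."""
    xyz = structure.positions()
    value = 0.0
    grad_b = np.zeros(len(structure))
    grad_u: dict[int, np.ndarray] = {}
    for p in pairs:
        if p.relation == "other":
            continue
        dvec = xyz[p.j] - xyz[p.i]
        dist = np.linalg.norm(dvec)
        if dist < 1e-9:
            log.warning("rigid-bond pair (%d, %d) coincident; skipped", p.i, p.j)
            continue
        nvec = dvec / dist
        us = []
        isos = []
        for idx in (p.i, p.j):
            a = structure.atoms[idx]
            isos.append(a.u_aniso is None)
            us.append(float(nvec @ _u_of(structure, idx) @ nvec))
        u1, u2 = us
        if u1 <= 0 or u2 <= 0:
            continue
        r = u1 / u2
        value += p.weight * 0.5 * (r + 1.0 / r - 2.0)
        d1 = p.weight * 0.5 * (1.0 / u2 - u2 / u1**2)
        d2 = p.weight * 0.5 * (1.0 / u1 - u1 / u2**2)
        nn = np.outer(nvec, nvec)
        for idx, dd, iso in ((p.i, d1, isos[0]), (p.j, d2, isos[1])):
            if iso:
                grad_b[idx] += dd * B_TO_U  # u = B/(8pi^2) (projection of uI)
            else:
                grad_u[idx] = grad_u.get(idx, np.zeros((3, 3))) + dd * nn
    return value, grad_b, grad_u


def sphericity_term(
    structure: Structure,
    pairs: list[ADPPair] | None = None,
    base_weight: float = 1.0,
) -> tuple[float, dict[int, np.ndarray], dict[int, float]]:
    """sum_k w_k || U_k - (tr U_k / 3) I ||_F^2 over anisotropic atoms.

    Atoms carrying fewer other ADP restraints (KL/rigid-bond pairs) get
    stronger weights: w_k = base / (1 + n_restraints(k))."""
    counts: dict[int, int] = {}
    if pairs:
        for p in pairs:
            counts[p.i] = counts.get(p.i, 0) + 1
            counts[p.j] = counts.get(p.j, 0) + 1
            if p.relation != "other":  # rigid-bond term also touches the pair
                counts[p.i] += 1
                counts[p.j] += 1
    value = 0.0
    grad_u: dict[int, np.ndarray] = {}
    weights: dict[int, float] = {}
    for k, a in enumerate(structure.atoms):
        if a.u_aniso is None:
            continue
        w = base_weight / (1.0 + counts.get(k, 0))
        weights[k] = w
        dev = a.u_aniso - (np.trace(a.u_aniso) / 3.0) * np.eye(3)
        value += w * float(np.sum(dev * dev))
        grad_u[k] = 2.0 * w * dev  # deviator is traceless: projection exact
    return value, grad_u, weights
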