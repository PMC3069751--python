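"""Covalent-geometry restraints: term construction from the dictionary and
residual/gradient/Gauss-Newton evaluation.

Each term contributes w (b_m - b_i)^2 with w = 1/sigma^2, where b_m is the
geometric parameter measured on the model (bond length, angle, signed chiral
volume, plane deviation, torsion with period-aware wrapping) and b_i its
dictionary ideal.  The Gauss-Newton Hessian is 2 J^T W J per term (no
second-order term).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .dictionary import RestraintDictionary
from .model import Structure

__all__ = [
    "GeometryTerm",
    "build_geometry_terms",
    "geometry_residual",
    "bond_rmsd",
    "bond_value",
    "angle_value",
    "torsion_value",
    "chirality_value",
]

log = logging.getLogger(__name__)

PEPTIDE_LINK_MAX = 2.5  # A; C(i)-N(i+1) guard for chain continuity
RAD2DEG = 180.0 / math.pi


@dataclass
class GeometryTerm:
    kind: str  # bond | angle | chirality | plane | torsion
    atoms: tuple[int, ...]
    ideal: float
    sigma: float
    period: int = 1
    label: str = ""

    @property
    def weight(self) -> float:
        return 1.0 / self.sigma**2


# ---------------------------------------------------------------------------
# geometric primitives (value + Jacobian w.r.t. the participating atoms)
# ---------------------------------------------------------------------------


def bond_value(x, grad=False):
    d = x[0] - x[1]
    r = np.linalg.norm(d)
    if not grad:
        return r
    u = d / r
    return r, np.array([u, -u])


def angle_value(x, grad=False):
    """Angle in degrees at x[1]; returns None for degenerate geometry."""
    u = x[0] - x[1]
    v = x[2] - x[1]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        return None
    c = np.dot(u, v) / (nu * nv)
    c = min(1.0, max(-1.0, c))
    theta = math.acos(c)
    if not grad:
        return theta * RAD2DEG
    s = math.sqrt(max(1.0 - c * c, 1e-16))
    if s < 1e-7:
        return None  # colinear: derivative ill-defined
    du = (v / (nu * nv) - c * u / nu**2) / -s
    dv = (u / (nu * nv) - c * v / nv**2) / -s
    jac = np.array([du, -(du + dv), dv]) * RAD2DEG
    return theta * RAD2DEG, jac


def torsion_value(x, grad=False):
    """Dihedral angle (degrees) of four points; analytic gradient."""
    b1 = x[1] - x[0]
    b2 = x[2] - x[1]
    b3 = x[3] - x[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or nb2 < 1e-9:
        return None
    phi = math.atan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2))
    if not grad:
        return phi * RAD2DEG
    # standard analytic dihedral derivatives (Blondel-Karplus form)
    g0 = -nb2 / np.dot(n1, n1) * n1
    g3 = nb2 / np.dot(n2, n2) * n2
    p = np.dot(b1, b2) / nb2**2
    q = np.dot(b3, b2) / nb2**2
    g1 = -(1.0 + p) * g0 + q * g3
    g2 = p * g0 - (1.0 + q) * g3
    jac = np.array([g0, g1, g2, g3]) * RAD2DEG
    return phi * RAD2DEG, jac


def chirality_value(x, grad=False):
    """Signed volume (x1-xc) . ((x2-xc) x (x3-xc)); x = (centre, n1, n2, n3)."""
    a = x[1] - x[0]
    b = x[2] - x[0]
    c = x[3] - x[0]
    v = float(np.dot(a, np.cross(b, c)))
    if not grad:
        return v
    da = np.cross(b, c)
    db = np.cross(c, a)
    dc = np.cross(a, b)
    return v, np.array([-(da + db + dc), da, db, dc])


def _plane_fit(x):
    centroid = x.mean(axis=0)
    dx = x - centroid
    _, _, vt = np.linalg.svd(dx, full_matrices=False)
    n = vt[-1]
    return n, centroid


def torsion_wrap(delta: float, period: int) -> float:
    """Minimal-image angular difference for a torsion of the given period."""
    span = 360.0 / period
    return (delta + span / 2.0) % span - span / 2.0


# ---------------------------------------------------------------------------
# term construction
# ---------------------------------------------------------------------------


def build_geometry_terms(
    structure: Structure,
    dictionary: RestraintDictionary,
    restrain_all_torsions: bool = False,
) -> list[GeometryTerm]:
    """Intra-residue terms from templates plus peptide-link terms between
    consecutive residues (C(i)-N(i+1) < 2.5 A guard).  Torsions are restrained
    only when flagged in the dictionary (omega, side-chain chi) unless
    ``restrain_all_torsions`` is set."""
    terms: list[GeometryTerm] = []
    for chain in structure.chain_ids:
        residues = structure.residues(chain)
        res_maps = []
        for resnum, resname, idx in residues:
            if resname.upper() not in dictionary.residues:
                raise KeyError(f"residue type {resname!r} not in dictionary")
            amap = {structure.atoms[i].name: i for i in idx}
            res_maps.append((resnum, resname.upper(), amap))
            tpl = dictionary.residue(resname)
            terms.extend(_template_terms(tpl, amap, None, f"{chain}/{resnum}",
                                         restrain_all_torsions))
        # peptide links between consecutive residues
        if "PEPTIDE" in dictionary.links:
            link = dictionary.link("PEPTIDE")
            for (rn1, name1, m1), (rn2, name2, m2) in zip(res_maps, res_maps[1:]):
                if name1 == "HOH" or name2 == "HOH" or "C" not in m1 or "N" not in m2:
                    continue
                d = np.linalg.norm(
                    structure.atoms[m1["C"]].pos - structure.atoms[m2["N"]].pos
                )
                if d >= PEPTIDE_LINK_MAX:
                    continue
                terms.extend(
                    _template_terms(link, m1, m2, f"{chain}/{rn1}-{rn2}",
                                    restrain_all_torsions)
                )
    return terms


def _template_terms(tpl, amap, next_amap, label, restrain_all):
    def resolve(name):
        if name.startswith("+"):
            if next_amap is None:
                return None
            return next_amap.get(name[1:])
        return amap.get(name)

    out = []
    for b in tpl.bonds:
        idx = tuple(resolve(n) for n in b.atoms)
        if None not in idx:
            out.append(GeometryTerm("bond", idx, b.ideal, b.sigma, label=label))
    for a in tpl.angles:
        idx = tuple(resolve(n) for n in a.atoms)
        if None not in idx:
            out.append(GeometryTerm("angle", idx, a.ideal, a.sigma, label=label))
    for c in tpl.chiralities:
        idx = tuple(resolve(n) for n in (c.centre,) + c.neighbours)
        if None not in idx:
            out.append(GeometryTerm("chirality", idx, c.ideal, c.sigma, label=label))
    for p in tpl.planes:
        idx = tuple(resolve(n) for n in p.atoms)
        if None not in idx:
            out.append(GeometryTerm("plane", idx, 0.0, p.sigma, label=label))
    for t in tpl.torsions:
        if not (t.restrained or restrain_all):
            continue
        idx = tuple(resolve(n) for n in t.atoms)
        if None not in idx:
            out.append(
                GeometryTerm("torsion", idx, t.ideal, t.sigma, period=t.period,
                             label=f"{label}:{t.name}")
            )
    return out


# ---------------------------------------------------------------------------
# residual evaluation
# ---------------------------------------------------------------------------


def geometry_residual(
    terms: list[GeometryTerm],
    coords: np.ndarray,
) -> tuple[float, np.ndarray, list[tuple[tuple[int, ...], np.ndarray]]]:
    """Total geometry residual, gradient and Gauss-Newton blocks.

    Returns ``(value, gradient (n_atoms, 3), blocks)`` where each block is
    ``(atom_indices, 2 w J^T J)`` of size (3m, 3m) for the m atoms of the
    term; value = sum w (b_m - b_i)^2, gradient = sum 2 w (b_m - b_i) J.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    value = 0.0
    grad = np.zeros_like(coords)
    blocks: list[tuple[tuple[int, ...], np.ndarray]] = []
    for term in terms:
        idx = term.atoms
        x = coords[list(idx)]
        w = term.weight
        if term.kind == "bond":
            b, jac = bond_value(x, grad=True)
            r = b - term.ideal
        elif term.kind == "angle":
            res = angle_value(x, grad=True)
            if res is None:
                log.warning("degenerate angle term %s skipped", term.label)
                continue
            b, jac = res
            r = b - term.ideal
        elif term.kind == "torsion":
            res = torsion_value(x, grad=True)
            if res is None:
                log.warning("degenerate torsion term %s skipped", term.label)
                continue
            b, jac = res
            r = torsion_wrap(b - term.ideal, term.period)
        elif term.kind == "chirality":
            b, jac = chirality_value(x, grad=True)
            r = b - term.ideal
        elif term.kind == "plane":
            n, centroid = _plane_fit(x)
            devs = (x - centroid) @ n
            # envelope theorem: the LS plane is stationary, so the exact
            # gradient treats (n, centroid) as fixed
            value += w * float(devs @ devs)
            m = len(idx)
            jrows = np.zeros((m, 3 * m))
            for a in range(m):
                jrows[a, 3 * a : 3 * a + 3] = n
            grad_flat = 2.0 * w * devs @ jrows
            for a, ai in enumerate(idx):
                grad[ai] += grad_flat[3 * a : 3 * a + 3]
            blocks.append((idx, 2.0 * w * jrows.T @ jrows))
            continue
        else:  # pragma: no cover
            raise ValueError(f"unknown term kind {term.kind}")
        value += w * r * r
        jflat = jac.reshape(-1)
        for a, ai in enumerate(idx):
            grad[ai] += 2.0 * w * r * jac[a]
        blocks.append((idx, 2.0 * w * np.outer(jflat, jflat)))
    return value, grad, blocks


def bond_rmsd(terms: list[GeometryTerm], coords: np.ndarray) -> float:
    """sqrt(mean (b_m - b_i)^2) over bond terms (the weight-selection metric)."""
    coords = np.asarray(coords, dtype=float)
    devs = [
        bond_value(coords[list(t.atoms)]) - t.ideal for t in terms if t.kind == "bond"
    ]
    if not devs:
        return 0.0
    return float(np.sqrt(np.mean(np.square(devs))))
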