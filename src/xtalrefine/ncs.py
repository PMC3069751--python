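"""Non-crystallographic symmetry: automatic detection, global and local
restraints, and the Geman-McClure robust estimator.

Detection pipeline: Needleman-Wunsch global sequence alignment of every chain
pair (match +1, mismatch -1, gap -2), acceptance thresholds on aligned length
(default 15), sequence identity (default 80%) and global superposition rmsd
(default 2.5 A); local rmsd over sliding 5-residue windows; waters/ligands
adopted into the correspondence when their transformed images superpose
within 1 A (re-run each refinement cycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .model import Structure

__all__ = [
    "NCSPair",
    "GMParams",
    "geman_mcclure",
    "procrustes_superpose",
    "detect_ncs",
    "local_rmsd",
    "global_ncs_residual",
    "local_ncs_residual",
    "build_local_ncs_pairs",
]

log = logging.getLogger(__name__)

THREE_TO_ONE = {
    "GLY": "G", "ALA": "A", "SER": "S", "CYS": "C", "HOH": "w", "LIG": "l",
}

LOCAL_PAIR_DMAX = 4.25  # A, shared with the jelly-body cutoff
WATER_ADOPTION_RADIUS = 1.0  # A


@dataclass
class GMParams:
    """Geman-McClure robustness scale (dimension of the residual)."""

    sigma_gm: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma_gm <= 0:
            raise ValueError("sigma_GM must be positive")


def geman_mcclure(r, sigma_gm: float):
    """rho(r) = r^2 / (1 + sigma^2 r^2), its slope, and a positive curvature
    proxy (Huber-style: the GN curvature with the residual treated at its
    current robust weight), guaranteeing descent directions.

    rho -> r^2 for small r and -> 1/sigma^2 as r -> inf.
    """
    if sigma_gm <= 0:
        raise ValueError("sigma_GM must be positive")
    r = np.asarray(r, dtype=float)
    den = 1.0 + sigma_gm**2 * r * r
    rho = r * r / den
    drho = 2.0 * r / den**2
    curv = 2.0 / den**2  # positive for all r
    return rho, drho, curv


@dataclass
class NCSPair:
    """A detected NCS relationship between two chains."""

    chain_a: str
    chain_b: str
    residue_pairs: list[tuple[int, int]]  # aligned (resnum_a, resnum_b)
    atom_pairs: np.ndarray  # (m, 2) atom indices (a -> b)
    rotation: np.ndarray  # (3,3), maps chain-a frame onto chain b
    translation: np.ndarray  # (3,)
    rmsd: float
    local_rmsd_value: float = np.nan
    identity: float = 100.0
    distance_pairs: np.ndarray | None = None  # (p, 4) i,j,i',j' for local NCS


def procrustes_superpose(a: np.ndarray, b: np.ndarray, weights=None):
    """Optimal proper rotation R and translation t minimizing
    sum w ||R a + t - b||^2 (Kabsch/SVD).  Returns (R, t, rmsd)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3:
        raise ValueError("need at least 3 point pairs")
    w = np.ones(len(a)) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    ca = (w[:, None] * a).sum(axis=0) / wsum
    cb = (w[:, None] * b).sum(axis=0) / wsum
    am = a - ca
    bm = b - cb
    h = (w[:, None] * am).T @ bm
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (colinear) point sets")
    dsign = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, dsign])
    r = vt.T @ diag @ u.T
    t = cb - r @ ca
    dev = (a @ r.T + t) - b
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", dev, dev)).sum() / wsum))
    return r, t, rmsd


def _chain_sequence(structure: Structure, chain: str):
    residues = [
        (rn, name, idx)
        for rn, name, idx in structure.residues(chain)
        if name.upper() not in ("HOH",)
    ]
    seq = "".join(THREE_TO_ONE.get(name.upper(), "X") for _, name, _ in residues)
    return residues, seq


def _align_sequences(seq_a: str, seq_b: str):
    """Needleman-Wunsch global alignment, match +1 / mismatch -1 / gap -2."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        pairs.extend(zip(range(s1, e1), range(s2, e2)))
    return pairs


def detect_ncs(
    structure: Structure,
    min_aligned: int = 15,
    min_identity: float = 80.0,
    max_rmsd: float = 2.5,
    window: int = 5,
    prepare_local: bool = False,
    gm: GMParams | None = None,
) -> list[NCSPair]:
    """Detect NCS-related chain pairs; empty list when nothing qualifies."""
    chains = [c for c in structure.chain_ids]
    out: list[NCSPair] = []
    for ia in range(len(chains)):
        for ib in range(ia + 1, len(chains)):
            pair = _detect_pair(
                structure, chains[ia], chains[ib], min_aligned, min_identity,
                max_rmsd, window,
            )
            if pair is not None:
                if prepare_local:
                    pair.distance_pairs = build_local_ncs_pairs(structure, pair)
                out.append(pair)
    return out


def _detect_pair(structure, ch_a, ch_b, min_aligned, min_identity, max_rmsd, window):
    res_a, seq_a = _chain_sequence(structure, ch_a)
    res_b, seq_b = _chain_sequence(structure, ch_b)
    if not seq_a or not seq_b:
        return None
    aligned = _align_sequences(seq_a, seq_b)
    if len(aligned) <= min_aligned:
        return None
    n_ident = sum(1 for i, j in aligned if seq_a[i] == seq_b[j])
    identity = 100.0 * n_ident / len(aligned)
    if identity <= min_identity:
        return None
    # matched atom pairs: common atom names per aligned residue
    atom_pairs = []
    residue_groups = []  # per aligned residue: list of (ia, ib)
    res_pairs = []
    for i, j in aligned:
        rn_a, _, idx_a = res_a[i]
        rn_b, _, idx_b = res_b[j]
        map_a = {structure.atoms[k].name: k for k in idx_a}
        map_b = {structure.atoms[k].name: k for k in idx_b}
        grp = [(map_a[nm], map_b[nm]) for nm in map_a if nm in map_b]
        if grp:
            residue_groups.append(grp)
            atom_pairs.extend(grp)
            res_pairs.append((rn_a, rn_b))
    if len(atom_pairs) < 3:
        return None
    ap = np.array(atom_pairs, dtype=int)
    xyz = structure.positions()
    r, t, rmsd = procrustes_superpose(xyz[ap[:, 0]], xyz[ap[:, 1]])
    if rmsd >= max_rmsd:
        return None
    pair = NCSPair(
        chain_a=ch_a,
        chain_b=ch_b,
        residue_pairs=res_pairs,
        atom_pairs=ap,
        rotation=r,
        translation=t,
        rmsd=rmsd,
        identity=identity,
    )
    _adopt_neighbours(structure, pair)
    pair.local_rmsd_value = local_rmsd(structure, pair, window=window)
    return pair


def _adopt_neighbours(structure: Structure, pair: NCSPair) -> None:
    """Add waters/ligands whose transformed images superpose within 1 A."""
    xyz = structure.positions()
    in_pair = set(pair.atom_pairs.ravel().tolist())
    extras_a = [
        i
        for i, a in enumerate(structure.atoms)
        if a.resname.upper() in ("HOH", "LIG") and i not in in_pair
    ]
    extras_b = [i for i in extras_a]
    if not extras_a:
        return
    added = []
    for i in extras_a:
        img = pair.rotation @ xyz[i] + pair.translation
        best, best_d = None, WATER_ADOPTION_RADIUS
        for j in extras_b:
            if j == i:
                continue
            dist = np.linalg.norm(img - xyz[j])
            if dist < best_d:
                best, best_d = j, dist
        if best is not None:
            added.append((i, best))
    if added:
        pair.atom_pairs = np.vstack([pair.atom_pairs, np.array(added, dtype=int)])


def local_rmsd(structure: Structure, pair: NCSPair, window: int = 5) -> float:
    """Average of per-window best-superposition rmsds over sliding windows of
    ``window`` aligned residues; with window >= alignment length this equals
    the global rmsd."""
    res_a = {rn: idx for rn, _, idx in structure.residues(pair.chain_a)}
    res_b = {rn: idx for rn, _, idx in structure.residues(pair.chain_b)}
    xyz = structure.positions()
    # per-residue atom pair groups, in alignment order
    groups = []
    for rn_a, rn_b in pair.residue_pairs:
        map_a = {structure.atoms[k].name: k for k in res_a.get(rn_a, [])}
        map_b = {structure.atoms[k].name: k for k in res_b.get(rn_b, [])}
        grp = [(map_a[nm], map_b[nm]) for nm in map_a if nm in map_b]
        if grp:
            groups.append(np.array(grp, dtype=int))
    n = len(groups)
    if n == 0:
        return np.nan
    k = min(window, n)
    rmsds = []
    for start in range(0, n - k + 1):
        ap = np.vstack(groups[start : start + k])
        try:
            _, _, r = procrustes_superpose(xyz[ap[:, 0]], xyz[ap[:, 1]])
        except ValueError:
            continue
        rmsds.append(r)
    return float(np.mean(rmsds)) if rmsds else np.nan


# ---------------------------------------------------------------------------
# restraint residuals
# ---------------------------------------------------------------------------


def update_transformations(structure: Structure, pairs: list[NCSPair]) -> None:
    """Re-estimate (R, t) of each pair from current coordinates (each cycle)."""
    xyz = structure.positions()
    for p in pairs:
        ap = p.atom_pairs
        p.rotation, p.translation, p.rmsd = procrustes_superpose(
            xyz[ap[:, 0]], xyz[ap[:, 1]]
        )


def global_ncs_residual(
    pairs: list[NCSPair],
    coords: np.ndarray,
    weight: float,
) -> tuple[float, np.ndarray, list[tuple[tuple[int, ...], np.ndarray]]]:
    """sum_pairs sum_atoms w ||R x_i + t - x_j||^2 with (R, t) held fixed in
    the derivatives (their dependence on the coordinates is ignored)."""
    coords = np.asarray(coords, dtype=float)
    value = 0.0
    grad = np.zeros_like(coords)
    blocks: list[tuple[tuple[int, ...], np.ndarray]] = []
    for p in pairs:
        r, t = p.rotation, p.translation
        for i, j in p.atom_pairs:
            dev = r @ coords[i] + t - coords[j]
            value += weight * float(dev @ dev)
            gi = 2.0 * weight * (r.T @ dev)
            gj = -2.0 * weight * dev
            grad[i] += gi
            grad[j] += gj
            jac = np.zeros((3, 6))
            jac[:, 0:3] = r
            jac[:, 3:6] = -np.eye(3)
            blocks.append(((int(i), int(j)), 2.0 * weight * jac.T @ jac))
    return value, grad, blocks


def build_local_ncs_pairs(structure: Structure, pair: NCSPair,
                          d_max: float = LOCAL_PAIR_DMAX) -> np.ndarray:
    """Corresponding intra-chain distance pairs (i, j, i', j') for local NCS:
    all corresponded atom pairs within ``d_max`` in chain A."""
    xyz = structure.positions()
    ap = pair.atom_pairs
    idx_a = ap[:, 0]
    out = []
    for u in range(len(ap)):
        for v in range(u + 1, len(ap)):
            i, ip = ap[u]
            j, jp = ap[v]
            if np.linalg.norm(xyz[i] - xyz[j]) <= d_max:
                out.append((i, j, ip, jp))
    return np.array(out, dtype=int).reshape(-1, 4)


def local_ncs_residual(
    pairs: list[NCSPair],
    coords: np.ndarray,
    gm: GMParams,
    weight: float,
) -> tuple[float, np.ndarray, list[tuple[tuple[int, ...], np.ndarray]]]:
    """sum w GM(d_ij(A) - d_i'j'(B)); robust to conformational changes."""
    coords = np.asarray(coords, dtype=float)
    value = 0.0
    grad = np.zeros_like(coords)
    blocks: list[tuple[tuple[int, ...], np.ndarray]] = []
    for p in pairs:
        if p.distance_pairs is None or len(p.distance_pairs) == 0:
            continue
        for i, j, ip, jp in p.distance_pairs:
            dij = coords[i] - coords[j]
            dpq = coords[ip] - coords[jp]
            na, nb = np.linalg.norm(dij), np.linalg.norm(dpq)
            if na < 1e-9 or nb < 1e-9:
                continue
            r = na - nb
            rho, drho, curv = geman_mcclure(r, gm.sigma_gm)
            value += weight * float(rho)
            ua, ub = dij / na, dpq / nb
            # d r / d x: +ua on i, -ua on j, -ub on i', +ub on j'
            grad[i] += weight * drho * ua
            grad[j] -= weight * drho * ua
            grad[ip] -= weight * drho * ub
            grad[jp] += weight * drho * ub
            jrow = np.concatenate([ua, -ua, -ub, ub])
            blocks.append(
                (
                    (int(i), int(j), int(ip), int(jp)),
                    weight * curv * np.outer(jrow, jrow),
                )
            )
    return value, grad, blocks
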