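"""External (known-structure) distance restraints and jelly-body restraints.

External restraints pull current interatomic distances toward targets from a
reference structure, through the Geman-McClure robust estimator:
    value = w_ext * sum GM((d_ij - d0_ij) / sigma_ij).
Restraint files are whitespace-separated rows
``chain1 resnum1 atom1 chain2 resnum2 atom2 dist sigma``; duplicate pairs
(multiple reference structures) combine by inverse-variance weighting, and
pairs beyond d_max in the reference are dropped.

Jelly-body restraints regularize the normal equations only: the current
interatomic distances act as targets, so the value and gradient contributions
are identically zero while the Gauss-Newton blocks change the search
direction (implicitly interpolating between individual-atom and rigid-body
refinement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import Structure
from .ncs import GMParams, geman_mcclure

__all__ = [
    "ExternalRestraint",
    "load_external_restraints",
    "external_residual",
    "jelly_body_contribution",
    "JELLY_DMAX",
]

log = logging.getLogger(__name__)

JELLY_DMAX = 4.25  # A (default pair cutoff, same-chain)


@dataclass
class ExternalRestraint:
    atom_i: int
    atom_j: int
    target: float  # d0_ij, A
    sigma: float
    n_sources: int = 1

    def __post_init__(self) -> None:
        if self.target <= 0 or self.sigma <= 0:
            raise ValueError("external restraint needs positive target and sigma")


def load_external_restraints(
    path: str,
    structure: Structure,
    d_max: float = 10.0,
) -> list[ExternalRestraint]:
    """Parse an external-restraint text file against a structure.

    Unresolvable atom references are skipped (counted, reported);
    reference distances above ``d_max`` are dropped; duplicated pairs are
    combined by inverse-variance weighting.
    """
    lookup = {(a.chain, a.resnum, a.name): i for i, a in enumerate(structure.atoms)}
    combined: dict[tuple[int, int], list[tuple[float, float]]] = {}
    n_skipped = 0
    n_dropped = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) != 8:
                n_skipped += 1
                continue
            key_i = (toks[0], int(toks[1]), toks[2])
            key_j = (toks[3], int(toks[4]), toks[5])
            d0, sig = float(toks[6]), float(toks[7])
            i = lookup.get(key_i)
            j = lookup.get(key_j)
            if i is None or j is None:
                n_skipped += 1
                continue
            if d0 > d_max:
                n_dropped += 1
                continue
            key = (min(i, j), max(i, j))
            combined.setdefault(key, []).append((d0, sig))
    if n_skipped:
        log.warning("external restraints: %d rows skipped (unresolvable)", n_skipped)
    if n_dropped:
        log.info("external restraints: %d rows beyond d_max dropped", n_dropped)
    out = []
    for (i, j), entries in combined.items():
        w = np.array([1.0 / s**2 for _, s in entries])
        d0 = float(np.sum([d * wi for (d, _), wi in zip(entries, w)]) / w.sum())
        sig = float(1.0 / np.sqrt(w.sum()))
        out.append(
            ExternalRestraint(atom_i=i, atom_j=j, target=d0, sigma=sig,
                              n_sources=len(entries))
        )
    return out


def external_residual(
    restraints: list[ExternalRestraint],
    coords: np.ndarray,
    w_ext: float,
    gm: GMParams,
) -> tuple[float, np.ndarray, list[tuple[tuple[int, ...], np.ndarray]]]:
    """w_ext * sum GM((d_ij - d0_ij)/sigma_ij) with GM chain-rule gradient and
    the positive curvature proxy for the Gauss-Newton blocks."""
    coords = np.asarray(coords, dtype=float)
    value = 0.0
    grad = np.zeros_like(coords)
    blocks: list[tuple[tuple[int, ...], np.ndarray]] = []
    for rst in restraints:
        dij = coords[rst.atom_i] - coords[rst.atom_j]
        d = np.linalg.norm(dij)
        if d < 1e-9:
            continue
        r = (d - rst.target) / rst.sigma
        rho, drho, curv = geman_mcclure(r, gm.sigma_gm)
        value += w_ext * float(rho)
        u = dij / d
        g = w_ext * drho / rst.sigma
        grad[rst.atom_i] += g * u
        grad[rst.atom_j] -= g * u
        jrow = np.concatenate([u, -u]) / rst.sigma
        blocks.append(
            ((rst.atom_i, rst.atom_j), w_ext * curv * np.outer(jrow, jrow))
        )
    return value, grad, blocks


def jelly_body_contribution(
    coords: np.ndarray,
    chain_of: np.ndarray,
    d_max: float = JELLY_DMAX,
    sigma: float = 0.02,
) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Gauss-Newton blocks ONLY for current-distance-as-target restraints on
    same-chain atom pairs within ``d_max``.

    Because each target equals the current distance, the residuals are all
    exactly zero: the function value and gradient contributions vanish by
    construction and only the second derivative (search direction) changes.
    """
    coords = np.asarray(coords, dtype=float)
    chain_of = np.asarray(chain_of)
    n = len(coords)
    w = 1.0 / sigma**2
    blocks: list[tuple[tuple[int, ...], np.ndarray]] = []
    # neighbour search on a coarse grid
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for i, j in sorted(tree.query_pairs(d_max)):
        if chain_of[i] != chain_of[j]:
            continue
        dij = coords[i] - coords[j]
        d = np.linalg.norm(dij)
        if d < 1e-9:
            continue
        u = dij / d
        jrow = np.concatenate([u, -u])
        blocks.append(((int(i), int(j)), 2.0 * w * np.outer(jrow, jrow)))
    return blocks
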