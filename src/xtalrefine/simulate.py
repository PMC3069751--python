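"""Deterministic generators for toy crystals and synthetic reflection data.

Everything is a pure function of (SimulationSpec, seed): polyalanine-like
chains built on ideal dictionary geometry (zero covalent residual), optional
NCS copies and heavy atoms, simulated amplitudes/intensities with Gaussian
noise, twinning applied on intensities, Friedel pairs with anomalous signal,
and unimodal Hendrickson-Lattman coefficients from a von Mises phase-error
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cell import UnitCell
from .dictionary import default_dictionary
from .model import Atom, Structure
from .reflections import ReflectionSet, generate_free_flags
from .scattering import direct_structure_factors
from .symmetry import SpaceGroupInfo

__all__ = [
    "SimulationSpec",
    "make_toy_structure",
    "make_polyala",
    "make_random_structure",
    "simulate_observations",
    "perturb_structure",
    "generate_hkl",
]


@dataclass
class SimulationSpec:
    """The conditions of a synthetic toy-crystal experiment."""

    spacegroup: str = "P 1"
    n_residues: int = 10
    n_atoms: int = 0  # random-atom mode when > 0 (overrides n_residues)
    d_min: float = 2.0
    noise: float = 0.0  # relative sigma on |F| (or on I in twin mode)
    cell_padding: float = 6.0
    b_iso: float = 20.0
    free_fraction: float = 0.05
    anomalous_element: str | None = None
    f_prime: float = 0.0
    f_double_prime: float = 0.0
    twin_operator: tuple | None = None
    twin_fraction: float = 0.0
    hl_kappa: float = 0.0  # von Mises concentration of the simulated phase error
    ncs_copy: bool = False
    ncs_angle_deg: float = 90.0
    ncs_translation: tuple = (15.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if not 0.0 <= self.twin_fraction <= 0.5:
            raise ValueError("twin fraction must be in [0, 0.5]")


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d given three predecessors: |cd| = bond, angle(b,c,d),
    torsion(a,b,c,d) (natural extension reference frame)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _cb_direction(u, v, ang_nu, ang_vu, left_handed=False):
    """Unit vector w with given angles to unit vectors u, v (the L-configured
    branch unless left_handed)."""
    cu = math.cos(math.radians(ang_nu))
    cv = math.cos(math.radians(ang_vu))
    uv = float(u @ v)
    # w = alpha u + beta v + gamma (u x v)/|u x v|
    det = 1.0 - uv * uv
    alpha = (cu - cv * uv) / det
    beta = (cv - cu * uv) / det
    rest = 1.0 - (alpha * alpha + beta * beta + 2 * alpha * beta * uv)
    gamma = math.sqrt(max(rest, 0.0))
    if left_handed:
        gamma = -gamma
    w = alpha * u + beta * v + gamma * np.cross(u, v) / math.sqrt(det)
    return w / np.linalg.norm(w)


def make_polyala(
    n_residues: int,
    chain: str = "A",
    phi: float = -57.0,
    psi: float = -47.0,
    b_iso: float = 20.0,
    start_resnum: int = 1,
) -> list[Atom]:
    """Polyalanine chain with exactly ideal dictionary geometry (helical
    torsions by default).  Residues carry N, CA, C, O, CB."""
    d = default_dictionary()
    ala = d.residue("ALA")
    bond = {tuple(sorted(b.atoms)): b.ideal for b in ala.bonds}
    ang = {a.atoms: a.ideal for a in ala.angles}
    link = d.link("PEPTIDE")
    b_cn = next(b.ideal for b in link.bonds if b.atoms == ("C", "+N"))
    a_cacn = next(a.ideal for a in link.angles if a.atoms == ("CA", "C", "+N"))
    a_cnca = next(a.ideal for a in link.angles if a.atoms == ("C", "+N", "+CA"))

    b_nca = bond[("CA", "N")]
    b_cac = bond[("C", "CA")]
    b_co = bond[("C", "O")]
    b_cacb = bond[("CA", "CB")]
    a_ncac = ang[("N", "CA", "C")]
    a_caco = ang[("CA", "C", "O")]
    a_ncacb = ang[("N", "CA", "CB")]
    a_cbcac = ang[("CB", "CA", "C")]

    atoms: list[Atom] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = n + np.array([b_nca, 0.0, 0.0])
    th = math.radians(a_ncac)
    c = ca + b_cac * np.array([-math.cos(th), math.sin(th), 0.0])
    backbone = []  # (N, CA, C) per residue
    for i in range(n_residues):
        if i > 0:
            n = _nerf(backbone[-1][0], backbone[-1][1], backbone[-1][2],
                      b_cn, a_cacn, psi)
            ca = _nerf(backbone[-1][1], backbone[-1][2], n, b_nca, a_cnca, 180.0)
            c = _nerf(backbone[-1][2], n, ca, b_cac, a_ncac, phi)
        backbone.append((n, ca, c))
    for i, (n, ca, c) in enumerate(backbone):
        rn = start_resnum + i
        atoms.append(Atom("N", chain, rn, "ALA", "N", n, b_iso=b_iso))
        atoms.append(Atom("C", chain, rn, "ALA", "CA", ca, b_iso=b_iso))
        atoms.append(Atom("C", chain, rn, "ALA", "C", c, b_iso=b_iso))
        if i + 1 < n_residues:
            n_next = backbone[i + 1][0]
            o = _nerf(n, ca, c, b_co, a_caco, _torsion_of(n, ca, c, n_next) + 180.0)
        else:
            o = _nerf(n, ca, c, b_co, a_caco, psi + 180.0)
        atoms.append(Atom("O", chain, rn, "ALA", "O", o, b_iso=b_iso))
        u = (n - ca) / np.linalg.norm(n - ca)
        v = (c - ca) / np.linalg.norm(c - ca)
        w = _cb_direction(u, v, a_ncacb, a_cbcac)
        atoms.append(Atom("C", chain, rn, "ALA", "CB", ca + b_cacb * w, b_iso=b_iso))
    return atoms


def _torsion_of(a, b, c, d):
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    return math.degrees(
        math.atan2(float(np.cross(n1, n2) @ b2) / np.linalg.norm(b2), float(n1 @ n2))
    )


def _cell_for(sg: SpaceGroupInfo, extent: np.ndarray, padding: float) -> UnitCell:
    a, b, c = extent + 2 * padding
    sym = sg.symbol
    if sym in ("P 31", "P 61", "R 3"):
        e = max(a, b)
        return UnitCell(e, e, c, 90.0, 90.0, 120.0)
    if sym == "P 41":
        e = max(a, b)
        return UnitCell(e, e, c)
    if sym == "C 2":
        return UnitCell(a, b, c, 90.0, 100.0, 90.0)
    return UnitCell(a, b, c)


def _rotation_z(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    return np.array(
        [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
    )


def make_toy_structure(spec: SimulationSpec) -> Structure:
    """Polyalanine chain (ideal geometry) or randomly packed atoms; optional
    NCS second copy and heavy atom.  Pure in (spec, seed)."""
    sg = SpaceGroupInfo(spec.spacegroup)
    rng = np.random.default_rng(spec.seed)
    if spec.n_atoms > 0:
        return make_random_structure(spec, sg, rng)
    atoms = make_polyala(spec.n_residues, chain="A", b_iso=spec.b_iso)
    xyz = np.array([a.pos for a in atoms])
    if spec.ncs_copy:
        r = _rotation_z(spec.ncs_angle_deg)
        t = np.asarray(spec.ncs_translation, dtype=float)
        centre = xyz.mean(axis=0)
        copies = [
            Atom(a.element, "B", a.resnum, a.resname, a.name,
                 r @ (a.pos - centre) + centre + t, occ=a.occ, b_iso=a.b_iso)
            for a in atoms
        ]
        atoms = atoms + copies
        xyz = np.array([a.pos for a in atoms])
    if spec.anomalous_element:
        # heavy atom rides as a single-atom ligand record
        pos = xyz.mean(axis=0) + rng.normal(0.0, 2.0, 3)
        atoms.append(
            Atom(spec.anomalous_element, "Z", 1, "LIG", "C1", pos, b_iso=spec.b_iso)
        )
    xyz = np.array([a.pos for a in atoms])
    lo = xyz.min(axis=0)
    for a in atoms:
        a.pos = a.pos - lo + spec.cell_padding
    extent = xyz.max(axis=0) - lo
    cell = _cell_for(sg, extent, spec.cell_padding)
    return Structure(cell=cell, spacegroup=sg, atoms=atoms)


def make_random_structure(spec: SimulationSpec, sg=None, rng=None) -> Structure:
    """Randomly packed carbon/nitrogen/oxygen atoms with a minimum-distance
    rejection rule (bounded retries)."""
    sg = sg or SpaceGroupInfo(spec.spacegroup)
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_atoms
    box = max(10.0, 2.2 * n ** (1.0 / 3.0) * 1.8)
    cell = _cell_for(sg, np.array([box, box, box]), 0.0)
    elements = rng.choice(["C", "N", "O"], size=n, p=[0.6, 0.2, 0.2])
    # keep sites inside a generous asymmetric-unit-sized region
    frac_hi = np.array([1.0 / max(len(sg) // 2, 1), 1.0, 1.0]) if len(sg) > 1 else np.ones(3)
    placed = []
    min_d = 1.8
    tries = 0
    while len(placed) < n and tries < 200 * n:
        tries += 1
        f = rng.uniform(0.05, 0.95, 3) * frac_hi
        x = cell.orthogonalize(f)
        if all(np.linalg.norm(x - p) >= min_d for p in placed):
            placed.append(x)
    if len(placed) < n:
        raise RuntimeError("could not pack atoms without clashes")
    bvals = rng.uniform(0.8 * spec.b_iso, 1.2 * spec.b_iso, n)
    atoms = [
        Atom(el, "A", i + 1, "LIG", "C1", placed[i], b_iso=float(bvals[i]))
        for i, el in enumerate(elements)
    ]
    return Structure(cell=cell, spacegroup=sg, atoms=atoms)


# ---------------------------------------------------------------------------
# reflections
# ---------------------------------------------------------------------------


def generate_hkl(cell: UnitCell, sg: SpaceGroupInfo, d_min: float) -> np.ndarray:
    """Unique ASU Miller indices to d_min (systematic absences removed)."""
    hmax = int(math.ceil(cell.a / d_min)) + 1
    kmax = int(math.ceil(cell.b / d_min)) + 1
    lmax = int(math.ceil(cell.c / d_min)) + 1
    h, k, l_ = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l_.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    hkl = hkl[d >= d_min]
    keep = [
        i
        for i, hh in enumerate(hkl)
        if sg.in_asu(hh) and not sg.is_systematically_absent(hh)
    ]
    return hkl[keep]


def simulate_observations(structure: Structure, spec: SimulationSpec) -> ReflectionSet:
    """Synthetic reflection data from a structure, per the spec conditions."""
    rng = np.random.default_rng(spec.seed + 1)
    sg = structure.spacegroup
    cell = structure.cell
    hkl = generate_hkl(cell, sg, spec.d_min)
    anomalous = None
    if spec.anomalous_element and (spec.f_prime or spec.f_double_prime):
        anomalous = {spec.anomalous_element: (spec.f_prime, spec.f_double_prime)}

    f_true = direct_structure_factors(structure, hkl, anomalous=anomalous)
    amp = np.abs(f_true)
    floor = 1e-3 * np.median(amp[amp > 0])

    free = generate_free_flags(hkl, spec.free_fraction, spec.seed)

    i_obs = sig_i = None
    f_plus = sig_plus = f_minus = sig_minus = None
    hl = None

    if spec.twin_operator is not None and spec.twin_fraction > 0:
        t = np.asarray(spec.twin_operator, dtype=int)
        a = spec.twin_fraction
        f2 = np.abs(direct_structure_factors(structure, hkl @ t)) ** 2
        i_true = (1.0 - a) * amp**2 + a * f2
        sig_i = np.maximum(spec.noise * i_true, floor**2)
        if spec.noise > 0:
            i_obs = i_true + rng.normal(0.0, 1.0, len(i_true)) * sig_i
        else:
            i_obs = i_true.copy()
            sig_i = np.maximum(sig_i, 1e-6 * np.median(i_true))
        f_obs = np.sqrt(np.clip(i_obs, 0.0, None))
        sig_f = np.maximum(sig_i / np.maximum(2.0 * f_obs, 1e-6), 1e-6)
    else:
        sig_f = np.maximum(spec.noise * amp, floor)
        f_obs = amp + (rng.normal(0.0, 1.0, len(amp)) * sig_f if spec.noise > 0 else 0.0)
        f_obs = np.abs(f_obs)

    if anomalous is not None:
        f_m = direct_structure_factors(structure, -hkl, anomalous=anomalous)
        ap, am = amp, np.abs(f_m)
        sp = np.maximum(spec.noise * ap, floor)
        sm = np.maximum(spec.noise * am, floor)
        noise_p = rng.normal(0.0, 1.0, len(ap)) * sp if spec.noise > 0 else 0.0
        noise_m = rng.normal(0.0, 1.0, len(am)) * sm if spec.noise > 0 else 0.0
        f_plus = np.abs(ap + noise_p)
        f_minus = np.abs(am + noise_m)
        sig_plus, sig_minus = sp, sm
        f_obs = 0.5 * (f_plus + f_minus)
        sig_f = 0.5 * np.sqrt(sp**2 + sm**2)

    if spec.hl_kappa > 0:
        alpha_true = np.angle(f_true)
        hl = np.zeros((len(hkl), 4))
        hl[:, 0] = spec.hl_kappa * np.cos(alpha_true)
        hl[:, 1] = spec.hl_kappa * np.sin(alpha_true)

    rset = ReflectionSet(
        cell=cell,
        spacegroup=sg,
        hkl=hkl,
        f_obs=f_obs,
        sig_f=sig_f,
        free=free,
        f_plus=f_plus,
        sig_plus=sig_plus,
        f_minus=f_minus,
        sig_minus=sig_minus,
        i_obs=i_obs,
        sig_i=sig_i,
        hl=hl,
    )
    if rset.hl is not None:
        rset.hl[rset.centric, 2:] = 0.0
    return rset


def perturb_structure(
    structure: Structure,
    coord_rmsd: float,
    b_offset: float = 0.0,
    b_jitter: float = 0.0,
    seed: int = 0,
) -> Structure:
    """Gaussian coordinate noise rescaled to the requested rmsd exactly
    (post-scaling); B values offset/jittered, kept positive."""
    if coord_rmsd < 0:
        raise ValueError("rmsd must be >= 0")
    out = structure.copy()
    rng = np.random.default_rng(seed)
    n = len(out)
    if coord_rmsd > 0 and n > 0:
        noise = rng.normal(0.0, 1.0, (n, 3))
        current = math.sqrt(float(np.mean(np.sum(noise**2, axis=1))))
        noise *= coord_rmsd / current
        out.set_positions(out.positions() + noise)
    if b_offset or b_jitter:
        for a in out.atoms:
            if a.u_aniso is None:
                a.b_iso = max(a.b_iso + b_offset + rng.normal(0.0, b_jitter), 1.0)
    return out
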