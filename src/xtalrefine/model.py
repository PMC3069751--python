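"""Atomic model: atoms, structures and PDB I/O.

Coordinates are Cartesian angstroms throughout; fractional coordinates appear
only at the structure-factor boundary.  ADPs are either an isotropic B (A^2)
or a symmetric 3x3 anisotropic U tensor (A^2, Cartesian basis).  Conversions
follow the PDB conventions: B = 8 pi^2 U_iso and ANISOU integers are U x 1e4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .cell import UnitCell
from .symmetry import SpaceGroupInfo

__all__ = [
    "Atom",
    "Structure",
    "read_structure",
    "write_structure",
    "b_to_u",
    "u_to_b",
    "KNOWN_ELEMENTS",
]

B_TO_U = 1.0 / (8.0 * math.pi**2)

#: Elements with tabulated form factors (scattering module contract).
KNOWN_ELEMENTS = ("H", "C", "N", "O", "S", "P", "SE", "FE", "HG")


def b_to_u(b: float) -> float:
    """Isotropic B (A^2) -> U_iso (A^2)."""
    return b * B_TO_U


def u_to_b(u: float) -> float:
    """U_iso (A^2) -> isotropic B (A^2)."""
    return u / B_TO_U


@dataclass
class Atom:
    """One atom: identity, position (Cartesian A), occupancy and ADP."""

    element: str
    chain: str
    resnum: int
    resname: str
    name: str
    pos: np.ndarray
    occ: float = 1.0
    b_iso: float = 20.0
    u_aniso: np.ndarray | None = None  # symmetric 3x3, A^2, Cartesian

    def __post_init__(self) -> None:
        self.element = self.element.upper()
        self.pos = np.asarray(self.pos, dtype=float)
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError(f"occupancy {self.occ} outside [0, 1] for atom {self.name}")
        if self.u_aniso is None and self.b_iso <= 0:
            raise ValueError(f"isotropic B must be positive (atom {self.name})")
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, dtype=float)
            if self.u_aniso.shape != (3, 3):
                raise ValueError("anisotropic U must be 3x3")

    @property
    def is_anisotropic(self) -> bool:
        return self.u_aniso is not None

    @property
    def u_equiv(self) -> float:
        """Equivalent isotropic U: tr(U)/3 for aniso atoms, B/(8 pi^2) otherwise."""
        if self.u_aniso is not None:
            return float(np.trace(self.u_aniso)) / 3.0
        return b_to_u(self.b_iso)

    @property
    def b_equiv(self) -> float:
        return u_to_b(self.u_equiv)

    def key(self) -> tuple:
        return (self.chain, self.resnum, self.name)

    def copy(self) -> "Atom":
        return replace(
            self,
            pos=self.pos.copy(),
            u_aniso=None if self.u_aniso is None else self.u_aniso.copy(),
        )


@dataclass
class Structure:
    """Unit cell + space group + ordered atom list, with optional group tags."""

    cell: UnitCell
    spacegroup: SpaceGroupInfo
    atoms: list[Atom]
    rigid_groups: dict[str, list[int]] = field(default_factory=dict)
    tls_groups: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [a.key() for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom identifier {dup}")
        n = len(self.atoms)
        for gname, idx in {**self.rigid_groups, **self.tls_groups}.items():
            if any(i < 0 or i >= n for i in idx):
                raise ValueError(f"group {gname!r} references non-existent atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def chain_atoms(self, chain: str) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.chain == chain]

    def positions(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])

    def set_positions(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        for a, p in zip(self.atoms, xyz):
            a.pos = p.copy()

    def b_values(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms])

    def occupancies(self) -> np.ndarray:
        return np.array([a.occ for a in self.atoms])

    def copy(self) -> "Structure":
        return Structure(
            cell=self.cell,
            spacegroup=self.spacegroup,
            atoms=[a.copy() for a in self.atoms],
            rigid_groups={k: list(v) for k, v in self.rigid_groups.items()},
            tls_groups={k: list(v) for k, v in self.tls_groups.items()},
        )

    def residues(self, chain: str) -> list[tuple[int, str, list[int]]]:
        """(resnum, resname, atom indices) per residue, in chain order."""
        out: list[tuple[int, str, list[int]]] = []
        for i, a in enumerate(self.atoms):
            if a.chain != chain:
                continue
            if out and out[-1][0] == a.resnum:
                out[-1][2].append(i)
            else:
                out.append((a.resnum, a.resname, [i]))
        return out


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def read_structure(path: str) -> Structure:
    """Read a PDB file (CRYST1 + ATOM/HETATM/ANISOU records) into a Structure."""
    with open(path) as fh:
        text = fh.read()
    if "CRYST1" not in text:
        raise ValueError(f"{path}: missing CRYST1 record")
    st = gemmi.read_pdb_string(text)
    cell = UnitCell(
        st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma
    )
    sg = SpaceGroupInfo(st.spacegroup_hm or "P 1")
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    elem = at.element.name.upper()
                    if elem not in KNOWN_ELEMENTS:
                        raise ValueError(
                            f"unknown element {elem!r} for atom "
                            f"{chain.name}/{res.seqid.num}/{at.name}"
                        )
                    u = None
                    if at.aniso.nonzero():
                        a_ = at.aniso
                        u = np.array(
                            [
                                [a_.u11, a_.u12, a_.u13],
                                [a_.u12, a_.u22, a_.u23],
                                [a_.u13, a_.u23, a_.u33],
                            ]
                        )
                    atoms.append(
                        Atom(
                            element=elem,
                            chain=chain.name,
                            resnum=res.seqid.num,
                            resname=res.name,
                            name=at.name,
                            pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occ=at.occ,
                            b_iso=at.b_iso,
                            u_aniso=u,
                        )
                    )
        break  # first model only
    if not atoms:
        raise ValueError(f"{path}: no ATOM records")
    return Structure(cell=cell, spacegroup=sg, atoms=atoms)


def _pdb_atom_name(name: str, element: str) -> str:
    # standard PDB alignment: element right-justified in cols 13-14
    if len(element) == 2 or len(name) == 4:
        return f"{name:<4.4s}"
    return f" {name:<3.3s}"


def write_structure(structure: Structure, path: str) -> None:
    """Write a Structure as a PDB file (CRYST1, ATOM, ANISOU, TER, END)."""
    c = structure.cell
    lines = [
        f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
        f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {structure.spacegroup.symbol:<11s}"
    ]
    serial = 0
    prev_chain = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain != prev_chain:
            lines.append("TER")
        prev_chain = a.chain
        serial += 1
        name4 = _pdb_atom_name(a.name, a.element)
        lines.append(
            f"ATOM  {serial:5d} {name4} {a.resname:<3.3s} {a.chain:1.1s}{a.resnum:4d}    "
            f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}{a.occ:6.2f}{a.b_iso:6.2f}"
            f"          {a.element:>2.2s}"
        )
        if a.u_aniso is not None:
            u = np.rint(a.u_aniso * 1.0e4).astype(int)
            lines.append(
                f"ANISOU{serial:5d} {name4} {a.resname:<3.3s} {a.chain:1.1s}{a.resnum:4d}  "
                f"{u[0,0]:7d}{u[1,1]:7d}{u[2,2]:7d}{u[0,1]:7d}{u[0,2]:7d}{u[1,2]:7d}"
                f"      {a.element:>2.2s}"
            )
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
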