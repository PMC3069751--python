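"""Minimal covalent restraint dictionary.

A plain-text format (documented in the shipped ``data/minimal_dictionary.txt``)
holds per-residue templates -- bonds, angles, chiral volumes, planes and
torsions -- plus link templates for inter-residue bonds (peptide link).  An
import shim reads the standard mmCIF ``_chem_comp_bond`` / ``_chem_comp_angle``
loops for the same residues.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

__all__ = [
    "BondEntry",
    "AngleEntry",
    "ChiralityEntry",
    "PlaneEntry",
    "TorsionEntry",
    "ResidueTemplate",
    "RestraintDictionary",
    "load_dictionary",
    "default_dictionary",
    "write_dictionary",
    "load_chem_comp_cif",
]


@dataclass(frozen=True)
class BondEntry:
    atoms: tuple[str, str]
    ideal: float
    sigma: float


@dataclass(frozen=True)
class AngleEntry:
    atoms: tuple[str, str, str]
    ideal: float  # degrees
    sigma: float


@dataclass(frozen=True)
class ChiralityEntry:
    centre: str
    neighbours: tuple[str, str, str]
    ideal: float  # signed volume, A^3
    sigma: float


@dataclass(frozen=True)
class PlaneEntry:
    atoms: tuple[str, ...]
    sigma: float


@dataclass(frozen=True)
class TorsionEntry:
    name: str
    atoms: tuple[str, str, str, str]
    ideal: float  # degrees
    period: int
    sigma: float
    restrained: bool = False


@dataclass
class ResidueTemplate:
    name: str
    atoms: list[str] = field(default_factory=list)
    bonds: list[BondEntry] = field(default_factory=list)
    angles: list[AngleEntry] = field(default_factory=list)
    chiralities: list[ChiralityEntry] = field(default_factory=list)
    planes: list[PlaneEntry] = field(default_factory=list)
    torsions: list[TorsionEntry] = field(default_factory=list)

    def validate(self) -> None:
        known = set(self.atoms)

        def check(names, what):
            for nm in names:
                base = nm[1:] if nm.startswith("+") else nm
                if not self.atoms:
                    continue
                if not nm.startswith("+") and base not in known:
                    raise ValueError(
                        f"{self.name}: {what} references unknown atom {nm!r}"
                    )

        seen_bonds = set()
        for b in self.bonds:
            if b.sigma <= 0:
                raise ValueError(f"{self.name}: bond sigma must be positive")
            key = tuple(sorted(b.atoms))
            if key in seen_bonds:
                raise ValueError(f"{self.name}: duplicate bond entry {b.atoms}")
            seen_bonds.add(key)
            check(b.atoms, "bond")
        seen_angles = set()
        for a in self.angles:
            if a.sigma <= 0:
                raise ValueError(f"{self.name}: angle sigma must be positive")
            key = (a.atoms[1],) + tuple(sorted((a.atoms[0], a.atoms[2])))
            if key in seen_angles:
                raise ValueError(f"{self.name}: duplicate angle entry {a.atoms}")
            seen_angles.add(key)
            check(a.atoms, "angle")
        for c in self.chiralities:
            if c.sigma <= 0:
                raise ValueError(f"{self.name}: chirality sigma must be positive")
            check((c.centre,) + c.neighbours, "chirality")
        for p in self.planes:
            if p.sigma <= 0:
                raise ValueError(f"{self.name}: plane sigma must be positive")
            check(p.atoms, "plane")
        for t in self.torsions:
            if t.sigma <= 0:
                raise ValueError(f"{self.name}: torsion sigma must be positive")
            if t.period < 1:
                raise ValueError(f"{self.name}: torsion period must be >= 1")
            check(t.atoms, "torsion")


@dataclass
class RestraintDictionary:
    residues: dict[str, ResidueTemplate] = field(default_factory=dict)
    links: dict[str, ResidueTemplate] = field(default_factory=dict)

    def residue(self, name: str) -> ResidueTemplate:
        try:
            return self.residues[name.upper()]
        except KeyError:
            raise KeyError(f"residue type {name!r} not in dictionary") from None

    def link(self, name: str = "PEPTIDE") -> ResidueTemplate:
        return self.links[name.upper()]


def _parse_block(tokens_iter, name, is_link):
    tpl = ResidueTemplate(name=name)
    for toks in tokens_iter:
        kw = toks[0].lower()
        if kw == "end":
            break
        if kw == "atoms":
            tpl.atoms.extend(toks[1:])
        elif kw == "bond":
            tpl.bonds.append(BondEntry((toks[1], toks[2]), float(toks[3]), float(toks[4])))
        elif kw == "angle":
            tpl.angles.append(
                AngleEntry((toks[1], toks[2], toks[3]), float(toks[4]), float(toks[5]))
            )
        elif kw == "chir":
            tpl.chiralities.append(
                ChiralityEntry(toks[1], (toks[2], toks[3], toks[4]), float(toks[5]), float(toks[6]))
            )
        elif kw == "plane":
            tpl.planes.append(PlaneEntry(tuple(toks[1:-1]), float(toks[-1])))
        elif kw == "torsion":
            restrained = len(toks) > 9 and toks[9].lower() == "restrain"
            tpl.torsions.append(
                TorsionEntry(
                    toks[1],
                    (toks[2], toks[3], toks[4], toks[5]),
                    float(toks[6]),
                    int(toks[7]),
                    float(toks[8]),
                    restrained,
                )
            )
        else:
            raise ValueError(f"unknown dictionary record {toks[0]!r} in {name}")
    tpl.validate()
    return tpl


def load_dictionary(path: str) -> RestraintDictionary:
    """Parse the documented plain-text dictionary format."""
    with open(path) as fh:
        lines = fh.readlines()
    tokens = []
    for ln, raw in enumerate(lines, 1):
        line = raw.split("#", 1)[0].strip()
        if line:
            tokens.append((ln, line.split()))
    d = RestraintDictionary()
    it = iter(tokens)
    stream = (t for _, t in tokens)
    for ln, toks in it:
        kw = toks[0].lower()
        if kw in ("residue", "link"):
            name = toks[1].upper()
            target = d.links if kw == "link" else d.residues
            if name in target:
                raise ValueError(f"duplicate {kw} entry {name} (line {ln})")
            block = []
            for ln2, toks2 in it:
                block.append(toks2)
                if toks2[0].lower() == "end":
                    break
            target[name] = _parse_block(iter(block), name, kw == "link")
        else:
            raise ValueError(f"unexpected record {toks[0]!r} at line {ln}")
    return d


def default_dictionary() -> RestraintDictionary:
    """The shipped minimal dictionary (GLY, ALA, SER, CYS, HOH, LIG + peptide link)."""
    ref = importlib.resources.files("xtalrefine.data") / "minimal_dictionary.txt"
    with importlib.resources.as_file(ref) as path:
        return load_dictionary(str(path))


def write_dictionary(d: RestraintDictionary, path: str) -> None:
    """Serialize a dictionary; ideal values round-trip bit-exactly (repr)."""
    out = []
    for kind, table in (("residue", d.residues), ("link", d.links)):
        for name, tpl in table.items():
            out.append(f"{kind} {name}")
            if tpl.atoms:
                out.append("  atoms " + " ".join(tpl.atoms))
            for b in tpl.bonds:
                out.append(f"  bond {b.atoms[0]} {b.atoms[1]} {b.ideal!r} {b.sigma!r}")
            for a in tpl.angles:
                out.append(
                    f"  angle {a.atoms[0]} {a.atoms[1]} {a.atoms[2]} {a.ideal!r} {a.sigma!r}"
                )
            for c in tpl.chiralities:
                out.append(
                    f"  chir {c.centre} {' '.join(c.neighbours)} {c.ideal!r} {c.sigma!r}"
                )
            for p in tpl.planes:
                out.append(f"  plane {' '.join(p.atoms)} {p.sigma!r}")
            for t in tpl.torsions:
                flag = "restrain" if t.restrained else "free"
                out.append(
                    f"  torsion {t.name} {' '.join(t.atoms)} {t.ideal!r} {t.period} "
                    f"{t.sigma!r} {flag}"
                )
            out.append("end")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def load_chem_comp_cif(path: str) -> RestraintDictionary:
    """Import shim for mmCIF ``_chem_comp_bond`` / ``_chem_comp_angle`` loops."""
    import gemmi.cif as cif

    doc = cif.read(str(path))
    d = RestraintDictionary()
    for block in doc:
        for row in block.find(
            "_chem_comp_bond.", ["comp_id", "atom_id_1", "atom_id_2", "value_dist", "value_dist_esd"]
        ):
            comp = row[0].upper()
            tpl = d.residues.setdefault(comp, ResidueTemplate(name=comp))
            tpl.bonds.append(BondEntry((row[1], row[2]), float(row[3]), float(row[4])))
        for row in block.find(
            "_chem_comp_angle.",
            ["comp_id", "atom_id_1", "atom_id_2", "atom_id_3", "value_angle", "value_angle_esd"],
        ):
            comp = row[0].upper()
            tpl = d.residues.setdefault(comp, ResidueTemplate(name=comp))
            tpl.angles.append(
                AngleEntry((row[1], row[2], row[3]), float(row[4]), float(row[5]))
            )
    for tpl in d.residues.values():
        tpl.validate()
    return d
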