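"""Space-group symmetry: operators, epsilon factors, centricity, ASU mapping.

A curated set of space groups is supported (see ``SUPPORTED_SPACE_GROUPS``).
Operator tables come from gemmi; group closure is verified on construction.
Reflection-level logic (epsilon, centric flag, restricted phase) is computed
here by brute-force enumeration over the point-group operators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import gemmi
import numpy as np

__all__ = ["SpaceGroupInfo", "SymOp", "SUPPORTED_SPACE_GROUPS"]

#: Curated space groups (Hermann-Mauguin, short form without spaces accepted too).
SUPPORTED_SPACE_GROUPS = (
    "P 1",
    "P 21",
    "C 2",
    "P 21 21 21",
    "P 31",
    "P 41",
    "P 61",
    "R 3",
)

_ALIASES = {
    "P1": "P 1",
    "P21": "P 21",
    "P 1 21 1": "P 21",
    "P1211": "P 21",
    "C2": "C 2",
    "C 1 2 1": "C 2",
    "C121": "C 2",
    "P212121": "P 21 21 21",
    "P31": "P 31",
    "P41": "P 41",
    "P61": "P 61",
    "R3": "R 3",
    "R 3 :H": "R 3",
    "H3": "R 3",
    "H 3": "R 3",
}


@dataclass(frozen=True)
class SymOp:
    """One symmetry operator: fractional rotation matrix + translation."""

    rot: np.ndarray  # (3,3) int
    tran: np.ndarray  # (3,) float, fractional

    def triplet(self) -> str:
        parts = []
        for i in range(3):
            s = ""
            for j, name in enumerate("xyz"):
                r = int(self.rot[i, j])
                if r:
                    sign = "+" if r > 0 and s else ("-" if r < 0 else "")
                    mag = "" if abs(r) == 1 else str(abs(r)) + "*"
                    s += f"{sign}{mag}{name}"
            t = Fraction(self.tran[i]).limit_denominator(24)
            if t:
                s += f"+{t}" if t > 0 else f"-{-t}"
            parts.append(s)
        return ",".join(parts)


def _canonical_symbol(symbol: str) -> str:
    sym = symbol.strip()
    if sym in SUPPORTED_SPACE_GROUPS:
        return sym
    if sym in _ALIASES:
        return _ALIASES[sym]
    compact = sym.replace(" ", "")
    for known in SUPPORTED_SPACE_GROUPS:
        if compact == known.replace(" ", ""):
            return known
    if compact in _ALIASES:
        return _ALIASES[compact]
    raise ValueError(
        f"unsupported space group {symbol!r}; supported: {', '.join(SUPPORTED_SPACE_GROUPS)}"
    )


class SpaceGroupInfo:
    """Symmetry operators of one of the supported space groups.

    Parameters
    ----------
    symbol : Hermann-Mauguin symbol, e.g. ``"P 21 21 21"`` (spaces optional).
    """

    def __init__(self, symbol: str):
        self.symbol = _canonical_symbol(symbol)
        self._gemmi_sg = gemmi.find_spacegroup_by_name(self.symbol)
        if self._gemmi_sg is None:  # pragma: no cover - curated list is resolvable
            raise ValueError(f"space group {symbol!r} not found")
        gops = self._gemmi_sg.operations()
        ops = []
        for op in gops:
            rot = np.array(op.rot, dtype=int) // gemmi.Op.DEN
            tran = np.array(op.tran, dtype=float) / gemmi.Op.DEN
            ops.append(SymOp(rot=rot, tran=tran))
        self.operators: list[SymOp] = ops
        # centring translations (gemmi expands them into the op list already for C2/R3)
        rots = {tuple(op.rot.ravel()) for op in ops}
        self.point_group_rotations: list[np.ndarray] = [
            np.array(r, dtype=int).reshape(3, 3) for r in sorted(rots)
        ]
        self._asu = gemmi.ReciprocalAsu(self._gemmi_sg)
        self._verify_group()

    # -- group structure ---------------------------------------------------

    def _verify_group(self) -> None:
        """Closure and identity checks on the rotation parts (construction-time)."""
        rots = {tuple(r.ravel()) for r in self.point_group_rotations}
        if tuple(np.eye(3, dtype=int).ravel()) not in rots:
            raise ValueError("symmetry operator list lacks the identity")
        for r1 in self.point_group_rotations:
            for r2 in self.point_group_rotations:
                if tuple((r1 @ r2).ravel()) not in rots:
                    raise ValueError("point-group rotations are not closed under composition")

    def __len__(self) -> int:
        return len(self.operators)

    def __repr__(self) -> str:
        return f"SpaceGroupInfo({self.symbol!r}, {len(self.operators)} ops)"

    # -- reflection-level logic --------------------------------------------

    def epsilon_and_centric(self, hkl) -> tuple[int, bool, float | None]:
        """Epsilon factor, centric flag and restricted phase (radians) for hkl.

        epsilon = number of point-group rotations fixing hkl (acting on row
        vectors, h' = h R); centric iff some rotation sends hkl to -hkl.  For
        centric reflections the restricted phase (mod pi) is returned,
        otherwise None.
        """
        h = np.asarray(hkl, dtype=int)
        if not h.any():
            raise ValueError("epsilon/centricity undefined for (0,0,0)")
        eps = 0
        centric = False
        phase = None
        for op in self.operators:
            himg = h @ op.rot
            if np.array_equal(himg, h):
                eps += 1
            if np.array_equal(himg, -h):
                centric = True
                if phase is None:
                    # restricted phase: alpha = pi * h.t + n*pi
                    phase = math.pi * float(h @ op.tran) % math.pi
        return eps, centric, phase

    def is_systematically_absent(self, hkl) -> bool:
        return self._gemmi_sg.operations().is_systematically_absent(list(map(int, hkl)))

    def asu_equivalent(self, hkl) -> tuple[tuple[int, int, int], bool]:
        """Map hkl to its reciprocal-ASU representative.

        Returns ``(hkl_asu, friedel_flipped)`` where the flag says the Friedel
        mate (−h) was used to reach the ASU.
        """
        h = tuple(int(x) for x in hkl)
        asu_h, isym = self._asu.to_asu(h, self._gemmi_sg.operations())
        # gemmi ISYM convention: even isym = Friedel-flipped
        return tuple(asu_h), (isym % 2 == 0)

    def in_asu(self, hkl) -> bool:
        return self._asu.is_in(tuple(int(x) for x in hkl))

    def equivalent_indices(self, hkl) -> list[tuple[tuple[int, int, int], float]]:
        """All (h R, h.t) images of hkl under the space-group operators."""
        h = np.asarray(hkl, dtype=int)
        return [(tuple((h @ op.rot).tolist()), float(h @ op.tran)) for op in self.operators]
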