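"""Unit cell: orthogonalization, fractionalization and reciprocal-space metrics.

Conventions
-----------
* Lengths in angstroms, angles in degrees.
* The orthogonalization matrix follows the PDB convention: the *a* axis lies
  along Cartesian x, *b* in the xy plane.
* ``frac = frac_matrix @ cart``; ``cart = orth_matrix @ frac``.
* The reciprocal-space vector of a Miller index h is
  ``s = orth_matrix^-T @ h`` (units 1/A), with ``|s| = 1/d``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["UnitCell"]


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    orth_matrix: np.ndarray = field(init=False, repr=False, compare=False)
    frac_matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must be in (0, 180) degrees")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        # PDB-convention orthogonalization
        v = math.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
        if v <= 0:
            raise ValueError("degenerate unit cell (zero volume)")
        orth = np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )
        object.__setattr__(self, "orth_matrix", orth)
        object.__setattr__(self, "frac_matrix", np.linalg.inv(orth))

    @property
    def volume(self) -> float:
        """Cell volume in A^3 (determinant of the orthogonalization matrix)."""
        return float(np.linalg.det(self.orth_matrix))

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional -> Cartesian (A). Accepts (..., 3)."""
        return np.asarray(frac) @ self.orth_matrix.T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        """Cartesian (A) -> fractional. Accepts (..., 3)."""
        return np.asarray(cart) @ self.frac_matrix.T

    def recip_vectors(self, hkl: np.ndarray) -> np.ndarray:
        """Reciprocal vectors s (1/A, Cartesian) for Miller indices (..., 3)."""
        return np.asarray(hkl, dtype=float) @ self.frac_matrix

    def s_squared(self, hkl: np.ndarray) -> np.ndarray:
        """|s|^2 = 1/d^2 for Miller indices (..., 3)."""
        s = self.recip_vectors(hkl)
        return np.einsum("...i,...i->...", s, s)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (A) per Miller index."""
        s2 = self.s_squared(hkl)
        return 1.0 / np.sqrt(s2)
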