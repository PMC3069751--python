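"""Atomic scattering factors: sum-of-Gaussians (4-Gaussian + constant).

f(s) = sum_k a_k exp(-b_k (|s|/2)^2) + c, with |s| = 1/d, so (|s|/2) is the
familiar sin(theta)/lambda.  Coefficients are the International Tables 1992
values, taken from gemmi's tables for the supported element set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .model import KNOWN_ELEMENTS

__all__ = ["FormFactorTable"]


def _it92(element: str) -> tuple[np.ndarray, np.ndarray, float]:
    coef = gemmi.Element(element.capitalize()).it92
    return np.array(coef.a), np.array(coef.b), float(coef.c)


@dataclass
class FormFactorTable:
    """Per-element Gaussian coefficients; defaults cover ``KNOWN_ELEMENTS``."""

    coefficients: dict[str, tuple[np.ndarray, np.ndarray, float]] = field(
        default_factory=lambda: {el: _it92(el) for el in KNOWN_ELEMENTS}
    )

    def __post_init__(self) -> None:
        for el, (a, b, c) in self.coefficients.items():
            z = gemmi.Element(el.capitalize()).atomic_number
            f0 = float(np.sum(a) + c)
            if z and abs(f0 - z) > 0.02 * z:
                raise ValueError(
                    f"form factor for {el} has f(0)={f0:.3f}, "
                    f"expected ~{z} (neutral-atom electron count)"
                )

    def __contains__(self, element: str) -> bool:
        return element.upper() in self.coefficients

    def evaluate(self, element: str, s2: np.ndarray) -> np.ndarray:
        """f(|s|) for an array of |s|^2 values (1/A^2)."""
        el = element.upper()
        if el not in self.coefficients:
            raise KeyError(f"no form factor tabulated for element {element!r}")
        a, b, c = self.coefficients[el]
        s2 = np.asarray(s2, dtype=float)
        return np.sum(a * np.exp(-b[None, :] * (s2[..., None] / 4.0)), axis=-1) + c
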