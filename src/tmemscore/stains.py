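"""Chromogen stain bases for optical-density unmixing.

A stain basis is a 3x3 matrix of unit optical-density (OD) vectors, one row
per chromogen (blue/CD31 vessels, brown/CD68 macrophages, red/Mena tumor
cells), columns the R, G, B absorbances.  Under the Beer-Lambert model a
pixel with chromogen concentrations c has OD = c @ basis and transmitted
intensity I = I0 * exp(-OD); unmixing is the linear inversion c = OD @
basis^{-1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StainBasis", "DEFAULT_BASIS"]

#: published-style OD vectors: hematoxylin-like blue, DAB-like brown,
#: AEC-like red (rows; will be renormalised to unit length)
_DEFAULT_VECTORS = np.array([
    [0.650, 0.704, 0.286],   # blue  / CD31 endothelium
    [0.269, 0.568, 0.778],   # brown / CD68 macrophages
    [0.274, 0.680, 0.680],   # red   / Mena tumor cells
])


@dataclass(frozen=True)
class StainBasis:
    """3x3 unit-row OD matrix; nonsingular within a condition-number bound."""

    matrix: np.ndarray
    max_condition: float = 1e6

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (3, 3):
            raise ValueError("stain basis must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain basis rows must be nonzero")
        m = m / norms[:, None]
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > self.max_condition:
            raise ValueError(
                f"stain basis is singular or ill-conditioned "
                f"(condition number {cond:.3g} > {self.max_condition:.3g})")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


DEFAULT_BASIS = StainBasis(_DEFAULT_VECTORS)
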