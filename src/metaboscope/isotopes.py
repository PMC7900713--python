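"""Natural-abundance correction of MIDs and percent-labeled computation.

An observed mass-isotopomer distribution mixes tracer-derived 13C with
naturally abundant 13C (~1.07%) on the unlabeled carbon positions.  The
forward model is linear: column j of the correction matrix is the binomial
mass-shift distribution contributed by the (n - j) unlabeled carbons of a
molecule with j tracer labels.  Correction inverts the model by non-negative
least squares.  Only the carbon skeleton is corrected; derivatization-atom
contributions are out of scope.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

log = logging.getLogger(__name__)

NATURAL_ABUNDANCE_13C = 0.0107


@dataclass
class MID:
    """Mass-isotopomer distribution M+0..M+n of one metabolite."""

    metabolite: str
    n_carbons: int
    intensities: np.ndarray
    corrected: bool = False
    residual: float = 0.0
    preclip: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.intensities) != self.n_carbons + 1:
            raise ValueError("MID length must be n_carbons + 1")

    def normalized(self) -> "MID":
        s = self.intensities.sum()
        if s <= 0:
            raise ValueError("cannot normalize an all-zero MID")
        return MID(self.metabolite, self.n_carbons, self.intensities / s,
                   self.corrected, self.residual, self.preclip)


def natural_abundance_matrix(n_carbons: int, q: float = NATURAL_ABUNDANCE_13C) -> np.ndarray:
    """Lower-triangular forward model mapping true MID -> observed MID.

    ``M[i, j] = P(i - j extra mass units from n - j unlabeled carbons)``
    with per-carbon 13C probability q; each column sums to 1.
    """
    if not (0.0 <= q < 0.5):
        raise ValueError("q must lie in [0, 0.5): heavier regimes are ill-posed")
    n = n_carbons
    m = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        k = np.arange(0, n - j + 1)
        m[j + k, j] = binom.pmf(k, n - j, q)
    return m


def correct_mid(observed: MID | np.ndarray, matrix: np.ndarray) -> MID:
    """Invert the natural-abundance forward model by NNLS and renormalize.

    Negative components are impossible by construction (NNLS); the raw NNLS
    solution is kept in ``preclip`` and the residual norm reported.
    """
    if isinstance(observed, MID):
        vec = observed.normalized().intensities
        name, n_c = observed.metabolite, observed.n_carbons
    else:
        vec = np.asarray(observed, dtype=float)
        vec = vec / vec.sum()
        name, n_c = "", len(vec) - 1
    if matrix.shape != (len(vec), len(vec)):
        raise ValueError("matrix and MID dimensions must match")
    x, rnorm = nnls(matrix, vec)
    preclip = x.copy()
    s = x.sum()
    if s <= 0:
        raise ValueError("degenerate correction: all-zero solution")
    return MID(name, n_c, x / s, corrected=True, residual=float(rnorm), preclip=preclip)


def percent_labeled(mid: MID, allow_uncorrected: bool = False) -> float:
    """Percent of the pool carrying >= 1 tracer 13C: 100 * (1 - M+0)."""
    if not mid.corrected and not allow_uncorrected:
        raise ValueError("MID must be natural-abundance corrected first "
                         "(pass allow_uncorrected=True to override)")
    frac = mid.normalized().intensities
    return 100.0 * (1.0 - float(frac[0]))
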