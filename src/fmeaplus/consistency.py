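"""Consistency screening of pairwise-comparison matrices.

Crisp matrices get Saaty's classical consistency ratio
``CR = CI / RI(n)`` with ``CI = (lambda_max - n) / (n - 1)``.  Fuzzy
matrices are screened with the Gogus–Boucher two-matrix variant: the TFN
matrix is split into a *middle* matrix of modal values and a *geometric*
matrix of support geometric means ``sqrt(l * u)``; each gets its own
consistency ratio (CRm, CRg) against random indices re-derived for those
two matrix populations.  A matrix is conventionally accepted when the
ratio(s) do not exceed 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import CrispComparisonMatrix, FuzzyComparisonMatrix

__all__ = [
    "ConsistencyReport",
    "RANDOM_INDICES",
    "crisp_consistency",
    "fuzzy_consistency",
]

# Random indices by matrix size.  "saaty" is the classical table;
# "gogus_boucher_m" / "gogus_boucher_g" are the re-simulated indices for
# the middle and geometric matrices of a triangular-fuzzy comparison
# matrix.  n=1,2 are identically zero (a 2x2 reciprocal matrix is always
# consistent).
RANDOM_INDICES: dict[str, dict[int, float]] = {
    "saaty": {
        1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
        8: 1.41, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56,
        14: 1.57, 15: 1.59,
    },
    "gogus_boucher_m": {
        1: 0.0, 2: 0.0, 3: 0.4890, 4: 0.7937, 5: 1.0720, 6: 1.1996,
        7: 1.2874, 8: 1.3410, 9: 1.3793, 10: 1.4095, 11: 1.4181,
        12: 1.4462, 13: 1.4555, 14: 1.4913, 15: 1.4986,
    },
    "gogus_boucher_g": {
        1: 0.0, 2: 0.0, 3: 0.1796, 4: 0.2627, 5: 0.3597, 6: 0.3818,
        7: 0.4090, 8: 0.4164, 9: 0.4348, 10: 0.4455, 11: 0.4536,
        12: 0.4776, 13: 0.4691, 14: 0.4804, 15: 0.4880,
    },
}


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics for one comparison matrix.

    ``crm``/``crg`` are populated only for fuzzy matrices (Gogus–Boucher);
    for a fuzzy report, ``lambda_max``, ``ci`` and ``cr`` refer to the
    middle (modal) matrix.
    """

    lambda_max: float
    ci: float
    cr: float
    n: int
    ri_table: str
    crm: float | None = None
    crg: float | None = None

    @property
    def max_fuzzy_cr(self) -> float:
        if self.crm is None or self.crg is None:
            raise ValueError("not a fuzzy consistency report")
        return max(self.crm, self.crg)


def principal_eigenvalue(values: np.ndarray) -> float:
    """Largest real part among the eigenvalues of a positive matrix.

    For positive matrices Perron–Frobenius guarantees this is the
    (simple, real) principal eigenvalue.
    """
    return float(np.max(np.linalg.eigvals(values).real))


def crisp_consistency(
    matrix: CrispComparisonMatrix, ri_table: str = "saaty"
) -> ConsistencyReport:
    """Saaty-style consistency ratio of a crisp reciprocal matrix.

    ``ri_table`` selects the random-index population: ``"saaty"`` for
    ordinary crisp matrices, ``"gogus_boucher_m"`` / ``"gogus_boucher_g"``
    for the middle and geometric matrices of a fuzzy judgment matrix.
    ``CR`` is defined as 0 for n = 2.
    """
    if ri_table not in RANDOM_INDICES:
        raise KeyError(
            f"unknown random-index table {ri_table!r}; "
            f"choose from {sorted(RANDOM_INDICES)}"
        )
    n = matrix.n
    table = RANDOM_INDICES[ri_table]
    if n not in table:
        raise ValueError(f"no random index tabulated for n={n} (max {max(table)})")
    lam = principal_eigenvalue(matrix.values)
    if n == 2:
        return ConsistencyReport(lam, 0.0, 0.0, n, ri_table)
    ci = (lam - n) / (n - 1)
    ri = table[n]
    cr = ci / ri if ri > 0 else 0.0
    return ConsistencyReport(lam, ci, cr, n, ri_table)


def fuzzy_consistency(fmatrix: FuzzyComparisonMatrix) -> ConsistencyReport:
    """Gogus–Boucher consistency of a fuzzy comparison matrix.

    Splits the TFN matrix into its modal matrix and its ``sqrt(l*u)``
    matrix and computes a consistency ratio for each against the
    population-matched random indices.
    """
    mid = crisp_consistency(fmatrix.middle_matrix(), "gogus_boucher_m")
    geo = crisp_consistency(fmatrix.geometric_matrix(), "gogus_boucher_g")
    return ConsistencyReport(
        lambda_max=mid.lambda_max,
        ci=mid.ci,
        cr=mid.cr,
        n=fmatrix.n,
        ri_table="gogus_boucher",
        crm=mid.cr,
        crg=geo.cr,
    )
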