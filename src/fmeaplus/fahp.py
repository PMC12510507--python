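"""Fuzzy AHP: panel aggregation, screening, extent analysis, composition.

The pipeline mirrors standard group fuzzy-AHP practice.  Each expert
supplies a reciprocal matrix of triangular fuzzy judgments; matrices whose
Gogus–Boucher consistency ratio exceeds a threshold (0.1 by convention)
are discarded; the surviving panel is aggregated cell-wise by the
geometric mean; local priority weights are extracted with Chang's extent
analysis; and sub-criterion weights are composed into global weights by
multiplying through the hierarchy.

Chang's method, in brief: from the aggregated matrix form row fuzzy sums
``R_i``, normalize them into synthetic extents
``S_i = R_i (sum_k R_k)^{-1}``, score each item by the minimum degree of
possibility ``d(i) = min_{j != i} V(S_i >= S_j)``, and normalize the
``d`` vector.  Items whose extent is dominated by every other can receive
weight exactly zero — a known property of the method, reported here as a
warning rather than an error.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .consistency import ConsistencyReport, fuzzy_consistency
from .fuzzy import TFN, possibility_degree
from .matrices import FuzzyComparisonMatrix, WeightVector

__all__ = [
    "ZeroPossibilityWarning",
    "aggregate_panel",
    "screen_experts",
    "extent_weights",
    "geometric_mean_weights",
    "global_weights",
    "FuzzyAhpWeights",
]

#: Conventional acceptance threshold for consistency ratios.
DEFAULT_CR_THRESHOLD = 0.1


class ZeroPossibilityWarning(UserWarning):
    """Raised when extent analysis assigns an item zero weight."""


def _check_same_items(matrices: Sequence[FuzzyComparisonMatrix]) -> tuple[str, ...]:
    if not matrices:
        raise ValueError("empty panel: at least one matrix is required")
    items = matrices[0].items
    for k, m in enumerate(matrices[1:], start=2):
        if m.items != items:
            raise ValueError(
                f"matrix {k} has items {m.items}, expected {items} "
                "(all panel matrices must share item set and order)"
            )
    return items


def aggregate_panel(
    matrices: Sequence[FuzzyComparisonMatrix],
) -> FuzzyComparisonMatrix:
    """Cell-wise geometric mean of an expert panel's fuzzy matrices.

    The mean is taken component-wise over (l, m, u) on the upper
    triangle; the lower triangle is completed by the reciprocal rule, so
    the aggregate is exactly reciprocal regardless of rounding in the
    inputs.
    """
    items = _check_same_items(matrices)
    stack = np.stack([m.values for m in matrices])  # (k, n, n, 3)
    geo = np.exp(np.log(stack).mean(axis=0))
    n = len(items)
    out = np.zeros_like(geo)
    out[np.arange(n), np.arange(n), :] = 1.0
    for i in range(n):
        for j in range(i + 1, n):
            l, m, u = geo[i, j]
            out[i, j] = (l, m, u)
            out[j, i] = (1.0 / u, 1.0 / m, 1.0 / l)
    return FuzzyComparisonMatrix(items, out)


def screen_experts(
    matrices: Sequence[FuzzyComparisonMatrix],
    cr_threshold: float = DEFAULT_CR_THRESHOLD,
) -> tuple[
    list[FuzzyComparisonMatrix],
    list[FuzzyComparisonMatrix],
    list[ConsistencyReport],
]:
    """Partition expert matrices into kept/excluded by fuzzy consistency.

    A matrix is excluded when ``max(CRm, CRg) > cr_threshold``.  Returns
    ``(kept, excluded, reports)`` with one report per input matrix, in
    input order.
    """
    _check_same_items(matrices)
    kept: list[FuzzyComparisonMatrix] = []
    excluded: list[FuzzyComparisonMatrix] = []
    reports: list[ConsistencyReport] = []
    for m in matrices:
        rep = fuzzy_consistency(m)
        reports.append(rep)
        (excluded if rep.max_fuzzy_cr > cr_threshold else kept).append(m)
    return kept, excluded, reports


def extent_weights(fmatrix: FuzzyComparisonMatrix) -> WeightVector:
    """Chang extent-analysis priority weights of a fuzzy matrix.

    Raises on an all-crisp matrix: with zero spread every possibility
    degree is 0 or 1 and the method degenerates to an indicator of the
    single largest row sum; use a crisp AHP weighting instead.
    """
    vals = fmatrix.values
    n = fmatrix.n
    rows = vals.sum(axis=1)  # row fuzzy sums R_i, shape (n, 3)
    if fmatrix.is_all_crisp() and not np.allclose(rows[:, 1], rows[0, 1]):
        # with zero spread every possibility degree is 0 or 1, so the
        # method collapses to an indicator of the largest row sum; only
        # the fully tied (symmetric) case remains well defined
        raise ValueError(
            "extent analysis degenerates on an all-crisp matrix (every "
            "off-diagonal entry has u == l): possibility degrees become "
            "0/1 indicators; use geometric_mean_weights or provide fuzzy "
            "judgments"
        )
    total = rows.sum(axis=0)  # grand fuzzy sum
    # synthetic extents S_i = R_i * total^{-1} = (l_i/Σu, m_i/Σm, u_i/Σl)
    extents = [
        TFN(rows[i, 0] / total[2], rows[i, 1] / total[1], rows[i, 2] / total[0])
        for i in range(n)
    ]
    d = np.array(
        [
            min(
                possibility_degree(extents[i], extents[j])
                for j in range(n)
                if j != i
            )
            for i in range(n)
        ]
    )
    zeros = [fmatrix.items[i] for i in np.flatnonzero(d == 0.0)]
    if zeros:
        warnings.warn(
            f"extent analysis assigned zero weight to {zeros}; this is a "
            "known property of the minimum-possibility rule when an "
            "item's extent is dominated by every other",
            ZeroPossibilityWarning,
            stacklevel=2,
        )
    return WeightVector.from_raw(fmatrix.items, d)


def geometric_mean_weights(fmatrix: FuzzyComparisonMatrix) -> WeightVector:
    """Fuzzy-geometric-mean weights with centroid defuzzification.

    Alternative to extent analysis for sensitivity checks: the fuzzy
    geometric mean of each row is normalized by the fuzzy total and
    defuzzified by the centroid before renormalization.
    """
    vals = fmatrix.values
    n = fmatrix.n
    r = np.prod(vals, axis=1) ** (1.0 / n)  # (n, 3) row geometric means
    total = r.sum(axis=0)
    crisp = np.stack(
        [r[:, 0] / total[2], r[:, 1] / total[1], r[:, 2] / total[0]], axis=1
    ).mean(axis=1)
    return WeightVector.from_raw(fmatrix.items, crisp)


def global_weights(
    parent: WeightVector, children: Mapping[str, WeightVector]
) -> WeightVector:
    """Compose local weights through the hierarchy.

    Each leaf's global weight is its parent's weight times its local
    weight; a parent item without children is itself a leaf and passes
    its weight through unchanged.  The result sums to one by
    construction.
    """
    items: list[str] = []
    weights: list[float] = []
    for k, pname in enumerate(parent.items):
        pw = float(parent.weights[k])
        child = children.get(pname)
        if child is None:
            items.append(pname)
            weights.append(pw)
            continue
        for cname, cw in zip(child.items, child.weights):
            if cname in items:
                raise ValueError(f"duplicate leaf label {cname!r} across factors")
            items.append(cname)
            weights.append(pw * float(cw))
    return WeightVector.from_raw(items, weights)


class FuzzyAhpWeights(BaseEstimator):
    """Panel-to-weights fuzzy AHP estimator.

    Fits on a list of expert ``FuzzyComparisonMatrix`` objects (all over
    the same items): screens inconsistent experts, aggregates the kept
    panel by geometric mean, checks the aggregate's consistency, and
    extracts priority weights.

    Parameters
    ----------
    method : {"extent", "geometric_mean"}
        Weight-extraction rule.  ``"extent"`` (Chang extent analysis) is
        the default and the normative path; the geometric-mean/centroid
        route is provided for sensitivity analysis.
    cr_threshold : float
        Expert matrices with ``max(CRm, CRg)`` above this are excluded.
    screen : bool
        Disable to aggregate all experts regardless of consistency.

    Attributes
    ----------
    weights_ : WeightVector
        Priority weights of the aggregated panel.
    aggregated_ : FuzzyComparisonMatrix
        Geometric-mean aggregate of the kept matrices.
    consistency_ : ConsistencyReport
        Gogus–Boucher report (CRm, CRg) of the aggregate.
    kept_, excluded_ : list of FuzzyComparisonMatrix
    expert_reports_ : list of ConsistencyReport
        Per-input-expert consistency reports (input order).
    """

    def __init__(
        self,
        method: str = "extent",
        cr_threshold: float = DEFAULT_CR_THRESHOLD,
        screen: bool = True,
    ):
        self.method = method
        self.cr_threshold = cr_threshold
        self.screen = screen

    def fit(self, X: Sequence[FuzzyComparisonMatrix], y=None) -> "FuzzyAhpWeights":
        if self.method not in ("extent", "geometric_mean"):
            raise ValueError(f"unknown method {self.method!r}")
        if isinstance(X, FuzzyComparisonMatrix):
            X = [X]
        X = list(X)
        if self.screen:
            kept, excluded, reports = screen_experts(X, self.cr_threshold)
        else:
            kept, excluded = X, []
            reports = [fuzzy_consistency(m) for m in X]
        if not kept:
            raise ValueError(
                "every expert matrix failed the consistency screen "
                f"(threshold {self.cr_threshold})"
            )
        self.kept_ = kept
        self.excluded_ = excluded
        self.expert_reports_ = reports
        self.aggregated_ = aggregate_panel(kept)
        self.consistency_ = fuzzy_consistency(self.aggregated_)
        extractor = extent_weights if self.method == "extent" else geometric_mean_weights
        self.weights_ = extractor(self.aggregated_)
        self.items_ = self.aggregated_.items
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the weight vector as an array."""
        return self.fit(X).weights_.weights
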