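"""Labelled pairwise-comparison matrices and weight vectors.

``FuzzyComparisonMatrix`` holds an n-by-n grid of triangular fuzzy numbers
over named items with a unit diagonal and (near-)reciprocal structure.
Published matrices are printed rounded to three decimals, so exact
reciprocity cannot be demanded of loaded data: a per-component absolute
tolerance (default 0.005) absorbs the rounding, and loaders can instead
treat the upper triangle as authoritative and recompute the lower triangle
by the TFN reciprocal rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fuzzy import TFN, TriangularFuzzyNumber

__all__ = [
    "FuzzyComparisonMatrix",
    "CrispComparisonMatrix",
    "WeightVector",
    "RECIPROCITY_TOL",
]

#: Default absolute per-component reciprocity tolerance (3-decimal rounding).
RECIPROCITY_TOL = 0.005


def _as_tfn_array(entries) -> np.ndarray:
    arr = np.asarray(entries, dtype=float)
    if arr.ndim != 3 or arr.shape[0] != arr.shape[1] or arr.shape[2] != 3:
        raise ValueError(f"expected an (n, n, 3) array of (l, m, u), got shape {arr.shape}")
    return arr


@dataclass(frozen=True, eq=False)
class FuzzyComparisonMatrix:
    """A labelled n-by-n matrix of positive triangular fuzzy judgments.

    Parameters
    ----------
    items
        Ordered item labels (criteria being compared).
    values
        ``(n, n, 3)`` array of ``(l, m, u)`` components.
    reciprocity_tol
        Absolute per-component tolerance used when validating that
        ``values[j, i]`` is the reciprocal of ``values[i, j]``.
    """

    items: tuple[str, ...]
    values: np.ndarray
    reciprocity_tol: float = RECIPROCITY_TOL

    def __post_init__(self) -> None:
        arr = _as_tfn_array(self.values)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "items", tuple(self.items))
        n = arr.shape[0]
        if len(self.items) != n:
            raise ValueError("item labels do not match matrix size")
        if n < 2:
            raise ValueError("comparison matrix needs at least 2 items")
        if len(set(self.items)) != n:
            raise ValueError("item labels must be unique")
        if np.any(arr[:, :, 0] <= 0):
            raise ValueError("comparison entries must be positive TFNs")
        if np.any(arr[:, :, 0] > arr[:, :, 1]) or np.any(arr[:, :, 1] > arr[:, :, 2]):
            raise ValueError("every entry must satisfy l <= m <= u")
        diag = arr[np.arange(n), np.arange(n), :]
        if not np.allclose(diag, 1.0, atol=1e-12):
            raise ValueError("diagonal entries must be (1, 1, 1)")
        # near-reciprocity: values[j,i] ~ (1/u_ij, 1/m_ij, 1/l_ij)
        expect = np.stack(
            [1.0 / arr[:, :, 2].T, 1.0 / arr[:, :, 1].T, 1.0 / arr[:, :, 0].T], axis=-1
        )
        dev = np.abs(arr - expect).max()
        if dev > self.reciprocity_tol:
            raise ValueError(
                f"matrix is not reciprocal within tolerance {self.reciprocity_tol} "
                f"(max deviation {dev:.4g})"
            )

    # -- constructors --------------------------------------------------

    @classmethod
    def from_upper_triangle(
        cls,
        items: Sequence[str],
        upper: Mapping[tuple[str, str], TriangularFuzzyNumber | Sequence[float]],
        reciprocity_tol: float = RECIPROCITY_TOL,
    ) -> "FuzzyComparisonMatrix":
        """Build an exactly reciprocal matrix from upper-triangle judgments.

        ``upper`` maps each ordered pair ``(item_i, item_j)`` with i before
        j in ``items`` to a TFN; the lower triangle is completed by the
        reciprocal rule and the diagonal set to (1, 1, 1).
        """
        items = tuple(items)
        n = len(items)
        idx = {name: k for k, name in enumerate(items)}
        arr = np.zeros((n, n, 3))
        arr[np.arange(n), np.arange(n), :] = 1.0
        seen = set()
        for (a, b), v in upper.items():
            if a not in idx or b not in idx:
                raise KeyError(f"unknown item in pair ({a}, {b})")
            i, j = idx[a], idx[b]
            if i >= j:
                raise ValueError(f"pair ({a}, {b}) is not in upper-triangle order")
            t = v if isinstance(v, TriangularFuzzyNumber) else TFN(*v)
            arr[i, j] = (t.l, t.m, t.u)
            arr[j, i] = tuple(t.inverse())
            seen.add((i, j))
        expected = {(i, j) for i in range(n) for j in range(i + 1, n)}
        missing = expected - seen
        if missing:
            names = ", ".join(f"({items[i]}, {items[j]})" for i, j in sorted(missing))
            raise ValueError(f"incomplete upper triangle; missing pairs: {names}")
        return cls(items, arr, reciprocity_tol)

    @classmethod
    def from_full(
        cls,
        items: Sequence[str],
        entries,
        mode: str = "complete",
        reciprocity_tol: float = RECIPROCITY_TOL,
    ) -> "FuzzyComparisonMatrix":
        """Build from a full printed matrix.

        ``mode="complete"`` (default) treats the upper triangle as
        authoritative and recomputes the lower triangle by the reciprocal
        rule, after checking the printed lower triangle agrees within
        ``reciprocity_tol``.  ``mode="strict"`` keeps both triangles as
        printed and only validates.
        """
        arr = _as_tfn_array(entries)
        if mode not in ("complete", "strict"):
            raise ValueError(f"unknown mode {mode!r}")
        probe = cls(tuple(items), arr, reciprocity_tol)  # validates as printed
        if mode == "strict":
            return probe
        n = arr.shape[0]
        out = arr.copy()
        for i in range(n):
            for j in range(i + 1, n):
                l, m, u = arr[i, j]
                out[j, i] = (1.0 / u, 1.0 / m, 1.0 / l)
        return cls(tuple(items), out, reciprocity_tol)

    # -- views ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.items)

    def entry(self, item_i: str, item_j: str) -> TriangularFuzzyNumber:
        i = self.items.index(item_i)
        j = self.items.index(item_j)
        return TFN(*self.values[i, j])

    def middle_matrix(self) -> "CrispComparisonMatrix":
        """Crisp matrix of modal values ``m_ij``."""
        return CrispComparisonMatrix(self.items, self.values[:, :, 1].copy())

    def geometric_matrix(self) -> "CrispComparisonMatrix":
        """Crisp matrix of support geometric means ``sqrt(l_ij * u_ij)``."""
        return CrispComparisonMatrix(
            self.items, np.sqrt(self.values[:, :, 0] * self.values[:, :, 2])
        )

    def permuted(self, order: Sequence[str]) -> "FuzzyComparisonMatrix":
        """Reindex rows/columns/labels by the given item order."""
        if sorted(order) != sorted(self.items):
            raise ValueError("order must be a permutation of the items")
        pos = [self.items.index(name) for name in order]
        return FuzzyComparisonMatrix(
            tuple(order), self.values[np.ix_(pos, pos)], self.reciprocity_tol
        )

    def is_all_crisp(self) -> bool:
        """True when every off-diagonal entry has zero spread (u == l)."""
        off = ~np.eye(self.n, dtype=bool)
        return bool(np.all(self.values[off, 0] == self.values[off, 2]))


@dataclass(frozen=True, eq=False)
class CrispComparisonMatrix:
    """A positive (near-)reciprocal crisp comparison matrix."""

    items: tuple[str, ...]
    values: np.ndarray
    reciprocity_tol: float = 0.05  # relative; crisp views of rounded data

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "items", tuple(self.items))
        n = arr.shape[0]
        if arr.ndim != 2 or arr.shape[1] != n:
            raise ValueError("crisp comparison matrix must be square")
        if len(self.items) != n:
            raise ValueError("item labels do not match matrix size")
        if np.any(arr <= 0):
            raise ValueError("entries must be positive")
        if not np.allclose(np.diag(arr), 1.0, atol=1e-12):
            raise ValueError("diagonal must be 1")
        rel = np.abs(arr * arr.T - 1.0).max()
        if rel > self.reciprocity_tol:
            raise ValueError(
                f"matrix is not reciprocal within relative tolerance "
                f"{self.reciprocity_tol} (max |a_ij*a_ji - 1| = {rel:.4g})"
            )

    @property
    def n(self) -> int:
        return len(self.items)


@dataclass(frozen=True, eq=False)
class WeightVector:
    """Nonnegative weights over labelled items, summing to one."""

    items: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "items", tuple(self.items))
        if w.ndim != 1 or len(w) != len(self.items):
            raise ValueError("weights must be a vector matching the item labels")
        if np.any(w < -1e-12):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum():.12g})")

    @classmethod
    def from_raw(cls, items: Sequence[str], raw: Sequence[float]) -> "WeightVector":
        """Normalize nonnegative raw scores into a weight vector."""
        raw = np.asarray(raw, dtype=float)
        total = raw.sum()
        if total <= 0:
            raise ValueError("raw scores must have a positive sum")
        return cls(tuple(items), raw / total)

    def __getitem__(self, item: str) -> float:
        return float(self.weights[self.items.index(item)])

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(self.items, self.weights)}

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {k: round(float(v), ndigits) for k, v in zip(self.items, self.weights)}

    def ranking(self) -> tuple[str, ...]:
        """Items ordered by decreasing weight (stable for ties)."""
        order = np.argsort(-self.weights, kind="stable")
        return tuple(self.items[i] for i in order)
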