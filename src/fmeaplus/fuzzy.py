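"""Triangular fuzzy numbers and the small algebra the FAHP machinery needs.

A triangular fuzzy number (TFN) ``A = (l, m, u)`` encodes an uncertain
judgment ratio: ``m`` is the most plausible value, ``l`` and ``u`` bound the
support.  Pairwise-comparison entries, their aggregates and the synthetic
extents of Chang's method are all TFNs, so everything downstream reduces to
the handful of operations defined here: piecewise-linear membership,
component-wise addition and (approximate) multiplication, the reciprocal
rule, centroid defuzzification and the degree of possibility ``V(A >= B)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "TriangularFuzzyNumber",
    "TFN",
    "possibility_degree",
]


@dataclass(frozen=True, slots=True)
class TriangularFuzzyNumber:
    """A triangular fuzzy number ``(l, m, u)`` with ``l <= m <= u``.

    Parameters
    ----------
    l, m, u
        Lower bound, modal value and upper bound of the membership
        triangle.  For use in comparison matrices all three must be
        positive (judgment ratios are positive); the constructor only
        enforces the ordering, positivity is checked where required.
    """

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        if not (self.l <= self.m <= self.u):
            raise ValueError(
                f"TFN requires l <= m <= u, got ({self.l}, {self.m}, {self.u})"
            )

    # -- basic queries -------------------------------------------------

    @property
    def is_crisp(self) -> bool:
        """True when the support collapses to a point (l == m == u)."""
        return self.l == self.u

    @property
    def is_positive(self) -> bool:
        return self.l > 0

    def membership(self, x: float) -> float:
        """Piecewise-linear membership grade of ``x`` in ``[0, 1]``.

        Rises linearly from ``l`` to 1 at ``m``, falls back to 0 at ``u``;
        0 outside the support.  A crisp TFN is the indicator of ``m``.
        """
        if self.is_crisp:
            return 1.0 if x == self.m else 0.0
        if x < self.l or x > self.u:
            return 0.0
        if x <= self.m:
            if self.m == self.l:  # left edge vertical
                return 1.0
            return (x - self.l) / (self.m - self.l)
        if self.u == self.m:  # right edge vertical
            return 1.0
        return (self.u - x) / (self.u - self.m)

    def centroid(self) -> float:
        """Centroid defuzzification: the mean ``(l + m + u) / 3``."""
        return (self.l + self.m + self.u) / 3.0

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return TriangularFuzzyNumber(self.l + other.l, self.m + other.m, self.u + other.u)

    def __mul__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        """Approximate product, component-wise; requires positive operands.

        This is the standard extent-analysis rule: exact interval
        multiplication would not keep the result triangular.
        """
        if not (self.is_positive and other.is_positive):
            raise ValueError("TFN multiplication requires positive operands")
        return TriangularFuzzyNumber(self.l * other.l, self.m * other.m, self.u * other.u)

    def inverse(self) -> "TriangularFuzzyNumber":
        """Reciprocal TFN ``(1/u, 1/m, 1/l)``; requires ``l > 0``."""
        if self.l <= 0:
            raise ValueError("TFN inverse requires l > 0")
        return TriangularFuzzyNumber(1.0 / self.u, 1.0 / self.m, 1.0 / self.l)

    def scale(self, k: float) -> "TriangularFuzzyNumber":
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return TriangularFuzzyNumber(self.l * k, self.m * k, self.u * k)

    def __iter__(self) -> Iterator[float]:
        yield self.l
        yield self.m
        yield self.u

    def __repr__(self) -> str:  # compact, matches the (l, m, u) notation
        return f"TFN({self.l:g}, {self.m:g}, {self.u:g})"


TFN = TriangularFuzzyNumber


def possibility_degree(a: TriangularFuzzyNumber, b: TriangularFuzzyNumber) -> float:
    """Degree of possibility ``V(a >= b)`` between two TFNs.

    The height of the intersection of the two membership triangles:
    1 when ``a.m >= b.m`` (including the tie, by continuity), 0 when the
    supports are disjoint with ``b`` entirely above ``a``, otherwise
    ``(b.l - a.u) / ((a.m - a.u) - (b.m - b.l))``.
    """
    if a.m >= b.m:
        return 1.0
    if b.l >= a.u:
        return 0.0
    return (b.l - a.u) / ((a.m - a.u) - (b.m - b.l))
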