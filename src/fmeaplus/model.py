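"""The weighted-FMEA risk model: taxonomy, scores, RPN, ALARP levels.

Classical FMEA scores a failure mode by the unweighted product
``O x S x D``.  The model here replaces each factor score by a weighted
sum over four sub-factor ratings (Likert-style, 1-10 by default), and
the risk priority number by the product of *weighted* factor scores

    RPN = (w_O * O) * (w_S * S) * (w_D * D)

with the weights elicited from an expert panel by fuzzy AHP.  The RPN is
then banded into acceptable / tolerable (ALARP) / unacceptable levels at
consensus thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import fixtures
from .matrices import WeightVector

__all__ = [
    "FACTOR_ORDER",
    "FmeaTaxonomy",
    "FailureModeRecord",
    "RiskResult",
    "RiskThresholds",
    "RISK_LEVELS",
    "default_taxonomy",
    "derive_taxonomy",
    "factor_score",
    "rpn",
    "classify",
    "assess",
    "level_summary",
    "FmeaPlusRiskModel",
]

FACTOR_ORDER = ("occurrence", "severity", "detectability")
RISK_LEVELS = ("acceptable", "tolerable_alarp", "unacceptable")


@dataclass(frozen=True)
class RiskThresholds:
    """ALARP band boundaries for the weighted RPN.

    ``rpn <= t_low`` is acceptable, ``t_low < rpn <= t_high`` tolerable
    (risk held as low as reasonably practicable), ``rpn > t_high``
    unacceptable.
    """

    t_low: float = fixtures.RISK_THRESHOLD_LOW
    t_high: float = fixtures.RISK_THRESHOLD_HIGH

    def __post_init__(self) -> None:
        if not (0 < self.t_low < self.t_high):
            raise ValueError("thresholds must satisfy 0 < t_low < t_high")


@dataclass(frozen=True)
class FmeaTaxonomy:
    """Three factors, four sub-factors each, with panel-derived weights."""

    factor_weights: WeightVector
    sub_factor_weights: Mapping[str, WeightVector]
    rating_scale: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        if set(self.factor_weights.items) != set(FACTOR_ORDER):
            raise ValueError(f"factors must be exactly {FACTOR_ORDER}")
        if set(self.sub_factor_weights) != set(FACTOR_ORDER):
            raise ValueError("sub_factor_weights must cover exactly the three factors")
        lo, hi = self.rating_scale
        if not lo < hi:
            raise ValueError("rating_scale must be (min, max) with min < max")
        seen: set[str] = set()
        for f, wv in self.sub_factor_weights.items():
            if len(wv.items) != 4:
                raise ValueError(f"factor {f!r} must have exactly 4 sub-factors")
            dup = seen & set(wv.items)
            if dup:
                raise ValueError(f"sub-factor labels duplicated across factors: {dup}")
            seen |= set(wv.items)

    @property
    def sub_factors(self) -> tuple[str, ...]:
        """All 12 sub-factor labels in factor order."""
        out: list[str] = []
        for f in FACTOR_ORDER:
            out.extend(self.sub_factor_weights[f].items)
        return tuple(out)

    def global_weights(self) -> WeightVector:
        """Leaf weights: parent factor weight times local sub-factor weight."""
        from .fahp import global_weights as _compose

        return _compose(self.factor_weights, dict(self.sub_factor_weights))


def default_taxonomy(rating_scale: tuple[float, float] = (1.0, 10.0)) -> FmeaTaxonomy:
    """The published panel-derived taxonomy.

    Factor weights 0.337 / 0.348 / 0.315 (occurrence, severity,
    detectability) and the four local sub-factor weights per factor, all
    exactly as tabulated (each printed vector sums to 1).
    """
    return FmeaTaxonomy(
        factor_weights=WeightVector(FACTOR_ORDER, np.array([0.337, 0.348, 0.315])),
        sub_factor_weights={
            "occurrence": WeightVector(
                fixtures.OCCURRENCE_SUBFACTORS, np.array([0.311, 0.247, 0.211, 0.231])
            ),
            "severity": WeightVector(
                fixtures.SEVERITY_SUBFACTORS, np.array([0.337, 0.257, 0.206, 0.200])
            ),
            "detectability": WeightVector(
                fixtures.DETECTABILITY_SUBFACTORS, np.array([0.324, 0.241, 0.218, 0.217])
            ),
        },
        rating_scale=rating_scale,
    )


def derive_taxonomy(
    factor_matrix,
    subfactor_matrices: Mapping[str, "object"],
    rating_scale: tuple[float, float] = (1.0, 10.0),
) -> FmeaTaxonomy:
    """Build a taxonomy from aggregated fuzzy matrices via extent analysis."""
    from .fahp import extent_weights

    fw = extent_weights(factor_matrix)
    # reorder onto the canonical factor order
    fw = WeightVector(FACTOR_ORDER, np.array([fw[f] for f in FACTOR_ORDER]))
    subs = {f: extent_weights(m) for f, m in subfactor_matrices.items()}
    return FmeaTaxonomy(fw, subs, rating_scale)


@dataclass(frozen=True)
class FailureModeRecord:
    """One failure mode with its 12 sub-factor ratings."""

    mode_id: str
    ratings: Mapping[str, float]
    description: str = ""

    def validate(self, taxonomy: FmeaTaxonomy) -> None:
        expected = set(taxonomy.sub_factors)
        got = set(self.ratings)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"mode {self.mode_id!r}: ratings do not match the taxonomy "
                f"(missing {missing}, unexpected {extra})"
            )
        lo, hi = taxonomy.rating_scale
        for k, v in self.ratings.items():
            if not (lo <= float(v) <= hi):
                raise ValueError(
                    f"mode {self.mode_id!r}: rating {k!r}={v} outside scale [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class RiskResult:
    """Weighted factor scores, RPN and ALARP level for one failure mode."""

    mode_id: str
    O: float
    S: float
    D: float
    rpn: float
    level: str


def factor_score(ratings: Mapping[str, float], weights: WeightVector) -> float:
    """Weighted factor score: the convex combination of sub-factor ratings."""
    missing = [k for k in weights.items if k not in ratings]
    extra = [k for k in ratings if k not in weights.items]
    if missing or extra:
        raise ValueError(
            f"ratings do not match weight items (missing {missing}, unexpected {extra})"
        )
    return float(sum(weights[k] * float(ratings[k]) for k in weights.items))


def rpn(
    O: float,
    S: float,
    D: float,
    factor_weights: WeightVector | None = None,
    rating_scale: tuple[float, float] = (1.0, 10.0),
) -> float:
    """Weighted risk priority number ``(w_O O)(w_S S)(w_D D)``."""
    if factor_weights is None:
        factor_weights = default_taxonomy().factor_weights
    lo, hi = rating_scale
    tol = 1e-9 * (hi - lo)  # weighted sums of boundary ratings round trip
    for name, v in (("O", O), ("S", S), ("D", D)):
        if not (lo - tol <= v <= hi + tol):
            raise ValueError(f"{name}={v} outside rating scale [{lo}, {hi}]")
    return (
        factor_weights["occurrence"] * O
        * factor_weights["severity"] * S
        * factor_weights["detectability"] * D
    )


def classify(rpn_value: float, thresholds: RiskThresholds | None = None) -> str:
    """ALARP band of an RPN value (boundaries belong to the lower band)."""
    if rpn_value < 0:
        raise ValueError("RPN must be nonnegative")
    t = thresholds or RiskThresholds()
    if rpn_value <= t.t_low:
        return "acceptable"
    if rpn_value <= t.t_high:
        return "tolerable_alarp"
    return "unacceptable"


def assess(
    records: Iterable[FailureModeRecord],
    taxonomy: FmeaTaxonomy | None = None,
    thresholds: RiskThresholds | None = None,
) -> list[RiskResult]:
    """Score every failure mode: weighted O, S, D, RPN and ALARP level."""
    taxonomy = taxonomy or default_taxonomy()
    thresholds = thresholds or RiskThresholds()
    results: list[RiskResult] = []
    for rec in records:
        rec.validate(taxonomy)
        scores = {
            f: factor_score(
                {k: rec.ratings[k] for k in taxonomy.sub_factor_weights[f].items},
                taxonomy.sub_factor_weights[f],
            )
            for f in FACTOR_ORDER
        }
        r = rpn(
            scores["occurrence"],
            scores["severity"],
            scores["detectability"],
            taxonomy.factor_weights,
            taxonomy.rating_scale,
        )
        results.append(
            RiskResult(
                mode_id=rec.mode_id,
                O=scores["occurrence"],
                S=scores["severity"],
                D=scores["detectability"],
                rpn=r,
                level=classify(r, thresholds),
            )
        )
    return results


def level_summary(results: Sequence[RiskResult]) -> dict[str, dict[str, float]]:
    """Counts and fractions of failure modes per ALARP level."""
    counts = {lvl: 0 for lvl in RISK_LEVELS}
    for r in results:
        counts[r.level] += 1
    total = len(results)
    fractions = {
        lvl: (counts[lvl] / total if total else 0.0) for lvl in RISK_LEVELS
    }
    return {"counts": counts, "fractions": fractions, "total": total}


class FmeaPlusRiskModel(BaseEstimator, TransformerMixin):
    """Weighted-FMEA risk scorer with a transformer/classifier surface.

    ``transform`` maps a DataFrame of sub-factor ratings (one row per
    failure mode, one column per sub-factor) to weighted O, S, D and RPN;
    ``predict`` returns the ALARP level per row.  ``fit`` freezes the
    taxonomy and thresholds; with no arguments the published weights and
    thresholds are used, so the model works out of the box yet composes
    with sklearn pipelines and ``clone``.

    Parameters
    ----------
    taxonomy : FmeaTaxonomy, optional
        Factor/sub-factor weights and rating scale; defaults to the
        published panel-derived taxonomy.
    thresholds : RiskThresholds, optional
        ALARP band boundaries; defaults to the published consensus values.
    """

    def __init__(
        self,
        taxonomy: FmeaTaxonomy | None = None,
        thresholds: RiskThresholds | None = None,
    ):
        self.taxonomy = taxonomy
        self.thresholds = thresholds

    def fit(self, X=None, y=None) -> "FmeaPlusRiskModel":
        self.taxonomy_ = self.taxonomy or default_taxonomy()
        self.thresholds_ = self.thresholds or RiskThresholds()
        self.feature_names_in_ = np.asarray(self.taxonomy_.sub_factors, dtype=object)
        if X is not None:
            self._records(X)  # validate eagerly
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "taxonomy_"):
            raise AttributeError("model is not fitted; call fit() first")

    def _records(self, X: pd.DataFrame) -> list[FailureModeRecord]:
        self._check_fitted()
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=list(self.taxonomy_.sub_factors))
        ids = [str(i) for i in X.index]
        recs = [
            FailureModeRecord(mode_id=i, ratings=row)
            for i, row in zip(ids, X.to_dict("records"))
        ]
        for r in recs:
            r.validate(self.taxonomy_)
        return recs

    def transform(self, X) -> pd.DataFrame:
        """Weighted O, S, D and RPN per failure mode."""
        recs = self._records(X)
        res = assess(recs, self.taxonomy_, self.thresholds_)
        return pd.DataFrame(
            {
                "O": [r.O for r in res],
                "S": [r.S for r in res],
                "D": [r.D for r in res],
                "rpn": [r.rpn for r in res],
            },
            index=[r.mode_id for r in res],
        )

    def predict(self, X) -> np.ndarray:
        """ALARP level per failure mode."""
        recs = self._records(X)
        res = assess(recs, self.taxonomy_, self.thresholds_)
        return np.asarray([r.level for r in res], dtype=object)

    def assess(self, X) -> tuple[list[RiskResult], dict]:
        """Full results plus the per-level summary."""
        recs = self._records(X)
        res = assess(recs, self.taxonomy_, self.thresholds_)
        return res, level_summary(res)
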