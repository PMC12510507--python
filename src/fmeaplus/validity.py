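"""Delphi-round, psychometric and outcome-validation statistics.

Supports the survey workflow around the risk model: Likert item means
and the strict ``> 4`` retention rule used to prune candidate
sub-factors, the coefficient-of-variation stopping rule for Delphi
rounds, Lawshe's content validity ratio, the content validity index
(I-CVI and S-CVI/Ave), Cronbach's alpha, and the contingency-table
statistics (prediction rates, Pearson chi-square) used to compare
predicted risk levels with observed accident outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LikertCountTable",
    "DelphiRoundResult",
    "likert_mean",
    "retention",
    "delphi_cv",
    "cvr",
    "cvi",
    "cronbach_alpha",
    "prediction_rate",
    "chi_square",
]

LIKERT_CATEGORIES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class LikertCountTable:
    """Per-item counts over the five Likert categories (1=Very Low .. 5=Very High)."""

    items: tuple[str, ...]
    counts: np.ndarray  # (n_items, 5) nonnegative integers
    n_experts: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "items", tuple(self.items))
        if arr.ndim != 2 or arr.shape != (len(self.items), 5):
            raise ValueError("counts must be an (n_items, 5) array")
        if np.any(arr < 0):
            raise ValueError("counts must be nonnegative")
        sums = arr.sum(axis=1)
        if np.any(sums != self.n_experts):
            bad = [self.items[i] for i in np.flatnonzero(sums != self.n_experts)]
            raise ValueError(
                f"counts must sum to n_experts={self.n_experts} for every item; "
                f"violated by {bad}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.items), columns=[f"c{k}" for k in LIKERT_CATEGORIES]
        )

    def means(self) -> dict[str, float]:
        return {item: likert_mean(row) for item, row in zip(self.items, self.counts)}


def likert_mean(counts: Sequence[int]) -> float:
    """Mean Likert score from category counts (categories scored 1-5)."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (5,):
        raise ValueError("expected 5 category counts")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("cannot take the mean of all-zero counts")
    return float(np.dot(LIKERT_CATEGORIES, c) / total)


def retention(mean: float, threshold: float = 4.0) -> bool:
    """Strict retention rule: keep an item iff its mean exceeds the threshold."""
    if not (1.0 <= mean <= 5.0):
        raise ValueError(f"Likert mean must lie in [1, 5], got {mean}")
    return mean > threshold


@dataclass(frozen=True)
class DelphiRoundResult:
    """Per-item and round-level coefficient of variation with stop flag."""

    item_cv: dict[str, float]
    cv: float
    stop: bool
    stop_threshold: float


def delphi_cv(
    scores: pd.DataFrame | np.ndarray,
    stop_threshold: float = 0.20,
    items: Sequence[str] | None = None,
) -> DelphiRoundResult:
    """Coefficient-of-variation stopping statistic for a Delphi round.

    ``scores`` is an expert-by-item matrix.  Per item, CV = sample
    standard deviation / mean; the round CV is the mean of the item CVs
    (the per-item values are kept so other aggregations can be audited).
    The round stops when CV falls below ``stop_threshold``.
    """
    if isinstance(scores, pd.DataFrame):
        items = list(scores.columns)
        arr = scores.to_numpy(dtype=float)
    else:
        arr = np.asarray(scores, dtype=float)
        if items is None:
            items = [f"item_{k}" for k in range(arr.shape[1])]
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 experts (rows)")
    means = arr.mean(axis=0)
    if np.any(means == 0):
        bad = [items[i] for i in np.flatnonzero(means == 0)]
        raise ValueError(f"zero-mean items make CV undefined: {bad}")
    sds = arr.std(axis=0, ddof=1)
    cvs = sds / np.abs(means)
    round_cv = float(cvs.mean())
    return DelphiRoundResult(
        item_cv={k: float(v) for k, v in zip(items, cvs)},
        cv=round_cv,
        stop=round_cv < stop_threshold,
        stop_threshold=stop_threshold,
    )


def cvr(n_essential: int, n_total: int) -> float:
    """Lawshe content validity ratio ``(n_e - N/2) / (N/2)`` in [-1, 1]."""
    if n_total < 1:
        raise ValueError("panel size must be at least 1")
    if not (0 <= n_essential <= n_total):
        raise ValueError("essential count must lie in [0, panel size]")
    half = n_total / 2.0
    return (n_essential - half) / half


def cvi(
    relevant_counts: Mapping[str, int] | Sequence[int],
    n_experts: int,
) -> tuple[dict[str, float], float]:
    """Content validity index: per-item I-CVI and the S-CVI/Ave average.

    ``relevant_counts`` gives, per item, the number of experts rating the
    item relevant.
    """
    if n_experts < 1:
        raise ValueError("need at least one expert")
    if not isinstance(relevant_counts, Mapping):
        relevant_counts = {f"item_{k}": c for k, c in enumerate(relevant_counts)}
    i_cvi: dict[str, float] = {}
    for item, c in relevant_counts.items():
        if not (0 <= c <= n_experts):
            raise ValueError(f"count for {item!r} outside [0, {n_experts}]")
        i_cvi[item] = c / n_experts
    if not i_cvi:
        raise ValueError("no items given")
    s_cvi_ave = float(np.mean(list(i_cvi.values())))
    return i_cvi, s_cvi_ave


def cronbach_alpha(scores: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha ``(k/(k-1)) (1 - sum item variances / total variance)``.

    ``scores`` is an expert-by-item matrix; sample variances (ddof=1)
    throughout.  Raises when the row totals have zero variance (alpha
    undefined).
    """
    arr = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(
        scores, dtype=float
    )
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 experts and 2 items")
    if np.isnan(arr).any():
        raise ValueError("missing values are not supported (listwise completeness)")
    k = arr.shape[1]
    item_vars = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def _as_contingency(table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.astype(float)
    else:
        arr = np.asarray(table, dtype=float)
        df = pd.DataFrame(arr)
    if (df.to_numpy() < 0).any():
        raise ValueError("contingency counts must be nonnegative")
    return df


def prediction_rate(
    table: pd.DataFrame,
    flagged_levels: Iterable[str],
) -> dict[str, int]:
    """Percent of each outcome column falling in the flagged predicted levels.

    ``table`` is a predicted-level (rows) by outcome-category (columns)
    contingency table of accident counts.  For each outcome the rate is
    the share of its accidents whose predicted risk level is flagged,
    rounded to the nearest integer percent.
    """
    df = _as_contingency(table)
    flagged = list(flagged_levels)
    missing = [lvl for lvl in flagged if lvl not in df.index]
    if missing:
        raise KeyError(f"flagged levels not in table rows: {missing}")
    out: dict[str, int] = {}
    for col in df.columns:
        total = df[col].sum()
        if total == 0:
            raise ValueError(f"outcome column {col!r} has no accidents")
        out[col] = int(round(100.0 * df.loc[flagged, col].sum() / total))
    return out


def chi_square(
    table: pd.DataFrame | np.ndarray,
    correction: bool = False,
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Returns ``(statistic, df, p)``.  Yates continuity correction is off
    by default; enable with ``correction=True``.
    """
    df = _as_contingency(table)
    arr = df.to_numpy()
    if arr.sum() == 0 or np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("every row and column must have a positive total")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)
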