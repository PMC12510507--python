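"""Synthetic expert panels, Likert rounds, worksheets and outcomes.

Every pipeline stage can be exercised end to end without survey data:
``synth_panel`` draws reciprocal fuzzy comparison matrices around a known
ground-truth weight vector (log-normal noise on the modal ratios, a
fixed relative spread for the TFN support), ``synth_likert`` draws
importance-survey counts from per-item category profiles,
``synth_worksheet`` draws failure-mode ratings, and ``synth_outcomes``
draws accident outcomes whose probability depends on the assessed risk
level.  All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matrices import FuzzyComparisonMatrix, WeightVector
from .model import FailureModeRecord, FmeaTaxonomy, RiskResult, RISK_LEVELS
from .validity import LikertCountTable

import pandas as pd

__all__ = [
    "PanelSpec",
    "OutcomeSpec",
    "synth_panel",
    "synth_likert",
    "synth_worksheet",
    "synth_outcomes",
    "saaty_scale_tfn",
]


def saaty_scale_tfn(x: float) -> tuple[float, float, float]:
    """Default linguistic-scale mapping ``x -> (x-1, x, x+1)`` clipped to [1, 9].

    For judgments below 1 the reciprocal of the scaled reciprocal
    judgment is returned, so the scale is self-consistent under
    inversion.  Used only by the synthesizer; the engine itself accepts
    TFNs directly.
    """
    if x <= 0:
        raise ValueError("judgment ratio must be positive")
    if x < 1:
        l, m, u = saaty_scale_tfn(1.0 / x)
        return (1.0 / u, 1.0 / m, 1.0 / l)
    return (max(x - 1.0, 1.0), min(x, 9.0), min(x + 1.0, 9.0))


@dataclass(frozen=True)
class PanelSpec:
    """Generator settings for a synthetic expert panel.

    ``spread`` is the relative half-width of each TFN support around its
    modal ratio; ``noise_sd`` the standard deviation of the log-normal
    perturbation of modal ratios between experts.  ``spread`` must be
    positive: a zero-spread (crisp) panel is rejected by extent analysis
    by design.
    """

    true_weights: WeightVector
    n_experts: int = 25
    spread: float = 0.3
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("need at least one expert")
        if not (self.spread > 0):
            raise ValueError(
                "spread must be positive: crisp (zero-spread) matrices are "
                "degenerate under extent analysis"
            )
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise ValueError("noise_sd must be finite and nonnegative")
        if np.any(self.true_weights.weights <= 0):
            raise ValueError("true weights must all be positive")


def synth_panel(spec: PanelSpec) -> list[FuzzyComparisonMatrix]:
    """Draw one reciprocal fuzzy comparison matrix per expert.

    Expert k's modal ratio for pair (i, j) is
    ``(w_i / w_j) * exp(noise)`` with ``noise ~ N(0, noise_sd^2)``; the
    TFN is ``(m (1 - spread), m, m (1 + spread))`` on the upper triangle
    and completed exactly reciprocally below.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.true_weights.weights
    items = spec.true_weights.items
    n = len(items)
    panel: list[FuzzyComparisonMatrix] = []
    for _ in range(spec.n_experts):
        arr = np.zeros((n, n, 3))
        arr[np.arange(n), np.arange(n), :] = 1.0
        for i in range(n):
            for j in range(i + 1, n):
                m = (w[i] / w[j]) * np.exp(rng.normal(0.0, spec.noise_sd))
                l, u = m * (1.0 - spec.spread), m * (1.0 + spec.spread)
                arr[i, j] = (l, m, u)
                arr[j, i] = (1.0 / u, 1.0 / m, 1.0 / l)
        panel.append(FuzzyComparisonMatrix(items, arr))
    return panel


def synth_likert(
    item_profiles: Mapping[str, Sequence[float]],
    n_experts: int,
    seed: int = 0,
) -> LikertCountTable:
    """Multinomial Likert counts from per-item category probabilities."""
    if n_experts < 1:
        raise ValueError("need at least one expert")
    rng = np.random.default_rng(seed)
    items = tuple(item_profiles)
    counts = np.zeros((len(items), 5), dtype=int)
    for k, item in enumerate(items):
        p = np.asarray(item_profiles[item], dtype=float)
        if p.shape != (5,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile for {item!r} must be 5 probabilities summing to 1")
        counts[k] = rng.multinomial(n_experts, p)
    return LikertCountTable(items, counts, n_experts)


def synth_worksheet(
    n_modes: int,
    taxonomy: FmeaTaxonomy,
    rating_distribution: str = "uniform",
    seed: int = 0,
) -> list[FailureModeRecord]:
    """Draw failure-mode worksheets valid against the taxonomy.

    Distributions: ``"uniform"`` over the rating scale,
    ``"triangular"`` peaked at mid-scale, ``"all_max"`` / ``"all_min"``
    degenerate extremes (useful for boundary checks).
    """
    if n_modes < 0:
        raise ValueError("n_modes must be nonnegative")
    lo, hi = taxonomy.rating_scale
    subs = taxonomy.sub_factors
    rng = np.random.default_rng(seed)
    if rating_distribution == "uniform":
        draw = lambda size: rng.uniform(lo, hi, size)
    elif rating_distribution == "triangular":
        draw = lambda size: rng.triangular(lo, (lo + hi) / 2.0, hi, size)
    elif rating_distribution == "all_max":
        draw = lambda size: np.full(size, float(hi))
    elif rating_distribution == "all_min":
        draw = lambda size: np.full(size, float(lo))
    else:
        raise ValueError(f"unknown rating distribution {rating_distribution!r}")
    records = []
    for k in range(n_modes):
        vals = draw(len(subs))
        records.append(
            FailureModeRecord(
                mode_id=f"FM{k + 1:03d}",
                ratings={s: float(v) for s, v in zip(subs, vals)},
                description=f"synthetic failure mode {k + 1}",
            )
        )
    return records


@dataclass(frozen=True)
class OutcomeSpec:
    """Accident-outcome generator settings.

    ``accident_prob`` maps each risk level to the probability that a
    failure mode of that level produces an accident within the
    observation window; ``severity_mix`` gives the probabilities of the
    outcome categories for an accident.
    """

    accident_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "acceptable": 0.05,
            "tolerable_alarp": 0.25,
            "unacceptable": 0.60,
        }
    )
    severity_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "without damage": 0.45,
            "minor damage": 0.42,
            "severe damage": 0.13,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for lvl in RISK_LEVELS:
            p = self.accident_prob.get(lvl)
            if p is None or not (0.0 <= p <= 1.0):
                raise ValueError(f"accident probability for {lvl!r} must be in [0, 1]")
        mix = np.asarray(list(self.severity_mix.values()), dtype=float)
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("severity mix must be probabilities summing to 1")


def synth_outcomes(results: Sequence[RiskResult], spec: OutcomeSpec) -> pd.DataFrame:
    """Risk-level by outcome-category accident contingency table.

    Per assessed failure mode an accident occurs with its level's
    probability; the accident's outcome category is drawn from the
    severity mix.  Rows are the three risk levels, columns the outcome
    categories; cells count accidents.
    """
    if not results:
        raise ValueError("need at least one assessed failure mode")
    rng = np.random.default_rng(spec.seed)
    cats = list(spec.severity_mix)
    p_cat = np.asarray([spec.severity_mix[c] for c in cats], dtype=float)
    table = pd.DataFrame(0, index=list(RISK_LEVELS), columns=cats, dtype=int)
    for r in results:
        if rng.random() < spec.accident_prob[r.level]:
            cat = cats[rng.choice(len(cats), p=p_cat)]
            table.loc[r.level, cat] += 1
    return table
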