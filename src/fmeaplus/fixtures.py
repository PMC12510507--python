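"""Packaged reference data for the weighted-FMEA risk model.

These are the published aggregated expert judgments behind the default
taxonomy: the panel-mean fuzzy comparison matrix of the three risk
factors, one matrix per factor for its four sub-factors, the Delphi
importance-survey counts used to prune the candidate sub-factors, and the
consensus ALARP thresholds.  All matrices are printed rounded to three
decimals; loaders treat the upper triangle as authoritative and complete
the lower triangle by the TFN reciprocal rule, which restores exact
reciprocity without altering the derived weights.
"""

from __future__ import annotations

from .matrices import FuzzyComparisonMatrix

__all__ = [
    "FACTORS",
    "OCCURRENCE_SUBFACTORS",
    "SEVERITY_SUBFACTORS",
    "DETECTABILITY_SUBFACTORS",
    "factor_matrix",
    "occurrence_matrix",
    "severity_matrix",
    "detectability_matrix",
    "subfactor_matrices",
    "delphi_importance_counts",
    "DELPHI_N_EXPERTS",
    "DELPHI_PRINTED_MEANS",
    "RISK_THRESHOLD_LOW",
    "RISK_THRESHOLD_HIGH",
]

FACTORS = ("occurrence", "severity", "detectability")

OCCURRENCE_SUBFACTORS = (
    "human reliability",
    "reliability",
    "incidents learning",
    "redundancy",
)
SEVERITY_SUBFACTORS = (
    "human injury",
    "financial loss",
    "operational interruption",
    "reputation damage",
)
DETECTABILITY_SUBFACTORS = (
    "technical inspection",
    "permanent maintenance",
    "daily/routine inspection",
    "employee participation",
)

# Published row order of the factor matrix is severity, detectability,
# occurrence; sub-factor matrices are in their published row orders.
_FACTOR_ROWS = ("severity", "detectability", "occurrence")
_FACTOR_ENTRIES = [
    [[1.000, 1.000, 1.000], [0.701, 0.980, 1.381], [0.778, 1.172, 1.652]],
    [[0.724, 1.021, 1.427], [1.000, 1.000, 1.000], [0.586, 0.837, 1.285]],
    [[0.605, 0.853, 1.295], [0.778, 1.195, 1.705], [1.000, 1.000, 1.000]],
]

_OCCURRENCE_ROWS = ("human reliability", "reliability", "incidents learning", "redundancy")
_OCCURRENCE_ENTRIES = [
    [[1.000, 1.000, 1.000], [0.803, 1.082, 1.412], [1.122, 1.716, 2.287], [0.772, 1.243, 1.831]],
    [[0.708, 0.924, 1.246], [1.000, 1.000, 1.000], [0.696, 1.000, 1.436], [0.781, 1.108, 1.536]],
    [[0.437, 0.583, 0.891], [0.696, 1.000, 1.436], [1.000, 1.000, 1.000], [0.687, 0.955, 1.300]],
    [[0.546, 0.804, 1.296], [0.651, 0.903, 1.281], [0.769, 1.047, 1.455], [1.000, 1.000, 1.000]],
]

_SEVERITY_ROWS = ("human injury", "financial loss", "operational interruption", "reputation damage")
_SEVERITY_ENTRIES = [
    [[1.000, 1.000, 1.000], [0.910, 1.268, 1.601], [1.195, 1.785, 2.287], [0.835, 1.324, 1.904]],
    [[0.624, 0.788, 1.099], [1.000, 1.000, 1.000], [0.791, 1.112, 1.554], [0.894, 1.271, 1.750]],
    [[0.437, 0.560, 0.837], [0.643, 0.900, 1.264], [1.000, 1.000, 1.000], [0.800, 1.099, 1.494]],
    [[0.525, 0.755, 1.197], [0.571, 0.787, 1.119], [0.669, 0.910, 1.250], [1.000, 1.000, 1.000]],
]

_DETECTABILITY_ROWS = (
    "technical inspection",
    "employee participation",
    "daily/routine inspection",
    "permanent maintenance",
)
_DETECTABILITY_ENTRIES = [
    [[1.000, 1.000, 1.000], [0.910, 1.268, 1.601], [1.195, 1.785, 2.287], [0.731, 1.149, 1.705]],
    [[0.624, 0.788, 1.099], [1.000, 1.000, 1.000], [0.665, 0.924, 1.326], [0.686, 0.942, 1.326]],
    [[0.437, 0.560, 0.837], [0.754, 1.082, 1.504], [1.000, 1.000, 1.000], [0.731, 1.020, 1.412]],
    [[0.586, 0.871, 1.369], [0.754, 1.061, 1.457], [0.708, 0.980, 1.369], [1.000, 1.000, 1.000]],
]


# The published factor matrix's lower triangle deviates from exact
# reciprocity by up to 0.0097 (one cell prints 1.295 where the reciprocal
# of the transpose cell is 1.2853); the sub-factor matrices stay within
# 0.0016.  A 0.01 tolerance admits all four as printed before the loader
# restores exact reciprocity from the upper triangle.
_PRINTED_TOL = 0.01


def factor_matrix(mode: str = "complete") -> FuzzyComparisonMatrix:
    """Aggregated 3x3 fuzzy matrix over severity/detectability/occurrence."""
    return FuzzyComparisonMatrix.from_full(
        _FACTOR_ROWS, _FACTOR_ENTRIES, mode=mode, reciprocity_tol=_PRINTED_TOL
    )


def occurrence_matrix(mode: str = "complete") -> FuzzyComparisonMatrix:
    """Aggregated 4x4 fuzzy matrix over the occurrence sub-factors."""
    return FuzzyComparisonMatrix.from_full(_OCCURRENCE_ROWS, _OCCURRENCE_ENTRIES, mode=mode)


def severity_matrix(mode: str = "complete") -> FuzzyComparisonMatrix:
    """Aggregated 4x4 fuzzy matrix over the severity sub-factors."""
    return FuzzyComparisonMatrix.from_full(_SEVERITY_ROWS, _SEVERITY_ENTRIES, mode=mode)


def detectability_matrix(mode: str = "complete") -> FuzzyComparisonMatrix:
    """Aggregated 4x4 fuzzy matrix over the detectability sub-factors."""
    return FuzzyComparisonMatrix.from_full(
        _DETECTABILITY_ROWS, _DETECTABILITY_ENTRIES, mode=mode
    )


def subfactor_matrices(mode: str = "complete") -> dict[str, FuzzyComparisonMatrix]:
    """Sub-factor matrices keyed by parent factor name."""
    return {
        "occurrence": occurrence_matrix(mode),
        "severity": severity_matrix(mode),
        "detectability": detectability_matrix(mode),
    }


# Delphi importance survey: per candidate sub-factor, counts of experts
# choosing Very Low / Low / Moderate / High / Very High (n = 35).
DELPHI_N_EXPERTS = 35

delphi_importance_counts: dict[str, tuple[int, int, int, int, int]] = {
    "reliability": (0, 0, 0, 4, 31),
    "redundancy": (0, 0, 0, 3, 32),
    "incidents learning": (0, 0, 0, 4, 31),
    "human reliability": (0, 0, 0, 5, 30),
    "human injury": (0, 0, 0, 4, 31),
    "financial loss": (0, 0, 0, 4, 31),
    "operational interruption": (0, 0, 0, 5, 30),
    "reputation damage": (0, 0, 0, 4, 31),
    "permanent maintenance": (0, 0, 0, 4, 31),
    "technical inspection": (0, 0, 0, 5, 30),
    "daily/routine inspection": (0, 0, 0, 4, 31),
    "permit data": (0, 2, 13, 8, 12),
    "employee participation": (0, 0, 0, 6, 29),
}

# Means as published.  "permit data" is printed as 3.743 although its
# printed counts give 3.857; both values fall below the >4 retention rule,
# so the pruning decision is unaffected.  The recomputed value is what
# likert_mean returns from the counts above.
DELPHI_PRINTED_MEANS: dict[str, float] = {
    "reliability": 4.886,
    "redundancy": 4.914,
    "incidents learning": 4.886,
    "human reliability": 4.857,
    "human injury": 4.886,
    "financial loss": 4.886,
    "operational interruption": 4.857,
    "reputation damage": 4.886,
    "permanent maintenance": 4.886,
    "technical inspection": 4.857,
    "daily/routine inspection": 4.886,
    "permit data": 3.743,
    "employee participation": 4.829,
}

# Consensus ALARP band boundaries for the weighted risk priority number.
RISK_THRESHOLD_LOW = 3.694
RISK_THRESHOLD_HIGH = 16.550
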