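# Methods

## The risk model

A failure mode is rated on twelve sub-factors grouped under occurrence,
severity and detectability (four each). Each factor score is the convex
combination of its sub-factor ratings with panel-derived local weights,

    O = Σᵢ Oᵢ·OWᵢ,   S = Σᵢ Sᵢ·SWᵢ,   D = Σᵢ Dᵢ·DWᵢ,

so a factor score always lies within the rating scale. The risk priority
number is the product of factor-weighted scores,

    RPN = (w_O·O)(w_S·S)(w_D·D),

which is strictly increasing in each factor and, on the default 1–10 scale
with the default weights (0.337, 0.348, 0.315), spans
[0.0369, 36.942]. RPN values are banded as acceptable (≤ 3.694),
tolerable/ALARP (≤ 16.550) or unacceptable (> 16.550); boundaries belong
to the lower band. The lower boundary coincides with
100 × w_O·w_S·w_D (i.e. `rpn(4, 5, 5)`); the upper boundary is a pure
consensus constant with no generative identity we could find, and both are
stored as configuration, not derived.

The rating scale is not fixed by the method; we default to the
FMEA-conventional 1–10 and accept non-integer ratings (scores may be
averages over assessors), validating only the bounds. The attainable RPN
range [0.0369, 36.942] is what the default weights imply; looser published
descriptions of the range are treated as rounding, not enforced.

Two published weight values conflict in their source: the severity
"financial loss" local weight appears both as 0.337 (prose) and 0.257
(table). We take 0.257: it is the only value under which the severity
vector sums to one, and it is the value extent analysis reproduces from
the severity comparison matrix.

## Weight elicitation (fuzzy AHP)

Judgments are triangular fuzzy numbers (TFNs) `A = (l, m, u)`, `l ≤ m ≤ u`,
with the usual piecewise-linear membership, component-wise addition,
approximate component-wise multiplication (valid for positive TFNs and
standard in extent analysis; exact interval products would not remain
triangular) and the reciprocal rule `(1/u, 1/m, 1/l)`.

Per hierarchy level, the pipeline is:

1. **Screening.** Each expert's reciprocal TFN matrix is split into its
   modal matrix and its `√(l·u)` matrix; each gets a Saaty-style
   consistency ratio `CR = (λ_max − n)/((n − 1)·RI(n))` with the
   Gogus–Boucher random indices re-simulated for those two populations
   (RIm(3) = 0.4890, RIg(3) = 0.1796, RIm(4) = 0.7937, RIg(4) = 0.2627,
   tabulated to n = 15). An expert is excluded when
   `max(CRm, CRg) > 0.1`. The source study reports only a single
   "inconsistency rate" rule; taking the maximum of the two ratios is the
   conservative reading and is what we implement. λ_max is the principal
   eigenvalue (Perron–Frobenius guarantees it is real and simple for
   positive matrices); for n = 3 it equals the closed form `1 + α + 1/α`
   with `α = (a₁₂a₂₃a₃₁)^{1/3}`, which the tests use as an independent
   check. CR is defined as 0 for n = 2.
2. **Aggregation.** The kept matrices are combined by the cell-wise,
   component-wise geometric mean on the upper triangle; the lower triangle
   is completed by the reciprocal rule, so the aggregate is exactly
   reciprocal whatever rounding the inputs carried.
3. **Extent analysis (Chang).** Row fuzzy sums `Rᵢ` are normalized by the
   grand sum into synthetic extents
   `Sᵢ = (Rᵢ.l/Σu, Rᵢ.m/Σm, Rᵢ.u/Σl)`; each item is scored by its minimum
   degree of possibility `d(i) = min_{j≠i} V(Sᵢ ≥ Sⱼ)` where `V` is the
   intersection-height formula (1 when the modal value dominates, with the
   tie returning 1 in both directions by continuity); weights are `d`
   normalized to sum one.
4. **Composition.** Global sub-factor weights are local weights times the
   parent factor weight; the twelve leaves sum to one by construction.

Two numerical edge cases are handled explicitly. An all-crisp matrix
(every off-diagonal `u = l`) with unequal row sums is refused: possibility
degrees degenerate to 0/1 and the method collapses to an indicator of the
largest row sum (the fully tied crisp case is well defined and returns
uniform weights). An item whose extent is dominated by every other
receives weight exactly zero; this is a known property of the
minimum-possibility rule and is reported as a structured warning, not an
error.

A geometric-mean/centroid weighting (fuzzy geometric mean of rows,
normalized by the fuzzy total, centroid-defuzzified) is available behind
`method="geometric_mean"` for sensitivity analysis. It is never the
default: on the packaged factor matrix it yields (0.346, 0.318, 0.336)
rather than the published (0.348, 0.315, 0.337), which only extent
analysis reproduces.

### Printed-matrix rounding

The packaged aggregated matrices are printed to three decimals, which
breaks exact reciprocity (one factor-matrix cell deviates by 0.0097 from
the reciprocal of its transpose; the sub-factor matrices stay within
0.0016). Matrix validation therefore accepts a configurable absolute
per-component reciprocity tolerance (default 0.005; the fixture loaders
pass 0.01), and by default treats the upper triangle as authoritative,
recomputing the lower triangle by the reciprocal rule. This completion
leaves every extent-analysis weight unchanged (verified for all four
packaged matrices) and moves the factor-matrix consistency ratios to
CRm = 0.0145, CRg = 0.0249 — the published values to printed precision —
where the matrix exactly as printed would give CRm = 0.0147,
CRg = 0.0273. A `mode="strict"` loader keeps both triangles as printed
and only validates.

## Survey statistics

- **Likert retention.** Item mean over categories scored 1–5; an item is
  retained iff its mean strictly exceeds 4. In the packaged importance
  survey this drops exactly one candidate sub-factor ("permit data"). That
  item's printed mean (3.743) disagrees with the mean of its printed
  counts (3.857); the fixture stores both, and since both fall below 4 the
  pruning decision is unaffected.
- **Delphi stopping.** Per-item coefficient of variation = sample SD /
  mean (ddof = 1); the round statistic is the mean of item CVs — the
  source reports a single round CV without naming an aggregation, so the
  mean is our choice and the per-item values are always reported so any
  other convention can be audited. The round stops when CV < 0.20.
- **Content validity.** Lawshe CVR `(n_e − N/2)/(N/2)`; CVI as I-CVI
  (proportion rating relevant) plus S-CVI/Ave (their mean), the common
  variant against the usual 0.79 benchmark. Published CVR/CVI figures
  cannot be reproduced exactly without per-item essential counts, which
  are not available; they serve as consistency checks only.
- **Cronbach's alpha.** `(k/(k−1))(1 − Σ item variances / variance of
  totals)` with sample variances; tests cross-check against a
  covariance-decomposition oracle and against pingouin.
- **Validation tables.** Prediction rate = percentage of each outcome
  column's accidents whose predicted level is flagged, rounded to integer
  percent; chi-square is Pearson's test of independence via scipy, without
  continuity correction unless requested.

## Synthetic data

The generators emulate the study's data shapes, not its plant. A panel
spec draws, per expert, modal ratios `(wᵢ/wⱼ)·exp(ε)` with
`ε ~ N(0, noise_sd²)` around a known weight vector, support half-width
`spread` relative to the mode, reciprocal completion exact by
construction. Defaults (`n_experts = 25, spread = 0.3, noise_sd = 0.15`)
mirror the study's scale: a 40-expert panel with 5 exclusions reduced to
35, moderate disagreement; at these settings extent analysis recovers the
true ranking in at least 95 of 100 seeds (a property the suite tests).
`spread > 0` is enforced because crisp panels are degenerate under extent
analysis. Likert rounds are multinomial draws from per-item category
profiles; worksheets draw ratings uniformly (or triangular-peaked, or at
the scale extremes) on the taxonomy's scale; outcomes draw one potential
accident per failure mode with a level-dependent probability
(0.05/0.25/0.60 by default, chosen to be monotone in risk level as any
validation design assumes) and a fixed severity mix. All generators are
pure functions of spec and seed.

What passing tests on these synthetics show: the pipeline's algebra,
screening, rank recovery under calibrated noise, and the monotone link
between assessed level and simulated outcomes. What they do not show:
anything about real accident processes — real expert noise is neither
log-normal nor independent across pairs, and real accident severity is
not independent of the failure mode.

## Problem sizes and determinism

All published-value reproductions run on the packaged 3×3 and 4×4
matrices and a 13-item survey; property checks use panels of up to 25
experts × 100 seeds and contingency tables of a few hundred modes. The
whole suite and the acceptance script complete in seconds. Every
stochastic path takes an explicit integer seed through
`numpy.random.default_rng`.

## Known limitations

- Extent analysis can assign exact zero weights to dominated items; users
  who need strictly positive weights should use the geometric-mean method
  and accept that it will not reproduce the published tables.
- The Gogus–Boucher random indices are tabulated to n = 15; larger
  matrices are rejected rather than extrapolated.
- The published per-accident validation data behind the reported
  chi-square p-values are not available at the printed level of
  aggregation, so the validation module is exercised on synthetic
  outcomes only.
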