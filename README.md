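# fmeaplus

Weighted Failure Mode and Effects Analysis for occupational-safety risk
assessment, with factor weights derived from expert panels by fuzzy AHP.

Classical FMEA ranks failure modes by the risk priority number
`RPN = O × S × D`, treating occurrence, severity and detectability as
equally important and each as a single monolithic rating. This package
implements a refinement developed for heavy industry in which

- each factor is decomposed into four rated sub-factors (for occurrence:
  human reliability, reliability, incidents learning, redundancy; analogous
  decompositions for severity and detectability),
- factor scores are weighted sums, e.g. `O = Σᵢ Oᵢ·OWᵢ`,
- the risk priority number is the product of *weighted* factor scores,

  `RPN = (w_O·O) × (w_S·S) × (w_D·D)`,  with default weights
  `w_O = 0.337, w_S = 0.348, w_D = 0.315`,

- and the RPN is banded by the ALARP principle: acceptable
  (`RPN ≤ 3.694`), tolerable (`3.694 < RPN ≤ 16.550`), unacceptable
  (`RPN > 16.550`).

All weights come from expert pairwise comparisons expressed as triangular
fuzzy numbers `(l, m, u)`: per-expert matrices are screened by the
Gogus–Boucher fuzzy consistency ratios (CRm on the modal matrix, CRg on the
`√(l·u)` matrix, both ≤ 0.1), aggregated cell-wise by geometric mean, and
weighted by Chang's extent analysis (row fuzzy sums → synthetic extents →
minimum degrees of possibility → normalization). The package also ships the
survey statistics used around such a study: Likert item means with a strict
`> 4` retention rule, the Delphi coefficient-of-variation stopping rule,
Lawshe's CVR, CVI, Cronbach's alpha, and contingency-table validation
(prediction rates, chi-square).

The audience is safety engineers and researchers building or auditing
multi-criteria risk models, and anyone who needs a tested reference
implementation of extent-analysis fuzzy AHP with consistency screening.

## Worked example

```python
import pandas as pd
from fmeaplus import FmeaPlusRiskModel, default_taxonomy

tax = default_taxonomy()          # published panel-derived weights
model = FmeaPlusRiskModel().fit()

ratings = pd.DataFrame(
    [{s: 8 for s in tax.sub_factors},      # a badly controlled mode
     {s: 4 for s in tax.sub_factors}],     # a moderate one
    index=["FM-CRANE-01", "FM-VALVE-07"],
)
print(model.transform(ratings))
print(model.predict(ratings))
```

```
               O    S    D        rpn
FM-CRANE-01  8.0  8.0  8.0  18.914273
FM-VALVE-07  4.0  4.0  4.0   2.364284
['unacceptable' 'acceptable']
```

With every sub-factor rated 8 the weighted scores are all 8, so
`RPN = (0.337·8)(0.348·8)(0.315·8) = 18.91 > 16.550` — the mode is
unacceptable and demands action; at ratings of 4 the RPN of 2.36 falls
below the 3.694 acceptability bound.

Weights can equally be re-derived from raw panels:

```python
from fmeaplus import FuzzyAhpWeights
from fmeaplus.fixtures import factor_matrix

est = FuzzyAhpWeights().fit([factor_matrix()])
print(est.weights_.rounded())   # {'severity': 0.348, 'detectability': 0.315, 'occurrence': 0.337}
print(round(est.consistency_.crm, 3), round(est.consistency_.crg, 3))  # 0.015 0.025
```

A `fmeaplus` console script exposes the same pipeline on CSV files
(`weights`, `assess`, `delphi`, `validate`, `synth`, `fixtures`); see
`fmeaplus --help`.

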