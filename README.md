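# treeletcox

Sparse fatty-acid pattern extraction and case-cohort survival analysis.

Fatty acids in adipose tissue share dietary sources and metabolic pathways,
so they occur in correlated patterns rather than varying independently.
`treeletcox` is for epidemiologists who want to analyze such patterns as
exposures: it extracts sparse, interpretable factors from a 32-channel
adipose-tissue fatty-acid panel with the **treelet transform**, scores
subjects on each pattern, and estimates sex-stratified hazard ratios for
atrial fibrillation across factor-score quintiles with **weighted Cox
regression under a case-cohort design** (age as the time axis, delayed
entry, Barlow weights, robust variance). A synthetic cohort generator with
the same statistical structure makes the whole pipeline testable without
registry data.

## The methods in brief

**Treelet transform.** Given the correlation matrix `C` of p z-scored
channels, repeatedly rotate the two most-correlated active coordinates by
the Givens angle θ, tan 2θ = 2c_ij/(c_ii − c_jj), which zeroes their
covariance; keep the higher-variance rotated coordinate active. The p − 1
merges form a dendrogram; cutting at level L and retaining the m
highest-variance basis vectors gives unit-norm loadings w_k that are sparse
by construction. Subject scores are s_k = w_kᵀ z. L and m are chosen by
K-fold cross-validation on the held-out captured variance Σ_k Var(w_kᵀz)/p.

**Case-cohort weighted Cox.** With all cases and a random subcohort
analyzed, the partial likelihood weights subcohort non-cases by
(non-cases in cohort)/(non-cases in subcohort) and cases by 1; cases outside
the subcohort enter the risk set just before their event age. Quintile
hazard ratios HR_q = exp(β_q) (quintile 1 reference) carry robust sandwich
95% CIs, and the trend p-value is the Wald test of the quintile index
entered as one continuous covariate. Adjustment ladder: Model 1 (baseline-age
quintiles), Model 1A (+ smoking, schooling, and restricted-cubic-spline
alcohol/BMI/waist), Model 2 (+ seven comorbidities).

## Worked example

```python
from treeletcox import (
    TreeletTransform, CaseCohortCox, cross_validate,
    generate_panel, generate_cohort, sample_case_cohort, true_block_scores,
)
import pandas as pd

# a subcohort-sized panel with seven correlated fatty-acid blocks
panel = generate_panel(3000, seed=2)

cv = cross_validate(panel, K=5, seed=11)
print(cv.chosen_cut_level, cv.chosen_m)
# 23 7

tt = TreeletTransform(cut_level=cv.chosen_cut_level,
                      n_factors=cv.chosen_m).fit(panel)
print([float(round(v, 1)) for v in tt.explained_variance_pct_],
      round(tt.cumulative_explained_pct_, 1))
# [16.4, 10.5, 8.8, 8.7, 8.7, 6.8, 5.1] 65.0
print(sorted(len(s) for s in tt.factors_.supports()))
# [2, 3, 4, 4, 4, 5, 8]
```

The cross-validation selects a cut at level 23 with seven factors; they
explain 65% of the panel variance, and the largest pattern (the
saturated-fat block) contains 8 fatty acids. Scoring and survival analysis:

```python
scores = pd.DataFrame(tt.transform(panel), index=panel.index,
                      columns=[f"TT{k+1}" for k in range(7)])
```

or run everything — simulation at full cohort scale (57,053 subjects,
subcohort 3,500), treelet + CV, scoring, and the sex-stratified Cox ladder —
from the shell:

```bash
treeletcox all --seed 3 --outdir run
# 7 factors at cut level 23, cumulative explained variance 65.1%
# artifacts under run
```

`run/` then contains the loadings table (`loadings.csv`, blanks for
structural zeros, explained-variance rows), per-sex hazard-ratio tables
(`hr_male.csv`, `hr_female.csv`; `1.00 (ref.)` first row per factor, a
`P(trend)` row last), subject scores, the dendrogram as JSON and Newick, the
CV score grid, and a provenance block (config hash, seed, version) embedded
in every file. Identical seed and config reproduce every artifact
byte-for-byte.

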