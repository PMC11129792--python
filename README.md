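# prsfactor

Integrating a polygenic risk score (PRS) into guideline-recommended
cardiovascular risk prediction.

Clinical tools such as SCORE2 estimate the *absolute* 10-year risk of a
first cardiovascular event from sex, age, systolic blood pressure, lipids
and smoking. A PRS instead measures *relative* genetic risk against the
population average. `prsfactor` implements a principled way of combining
the two:

1. **PRS-factor.** Rank a cohort into tenths of the PRS distribution
   (`PRS_j = Σ_i S_i G_ij` over effect-allele dosages, with missing
   dosages imputed as twice the reference allele frequency). Merge the
   fifth and sixth tenths into a reference group (OR = 1) and estimate the
   CVD odds ratio of each other tenth against it,

   `OR_ij = (D_ij / D_{5/6,j}) / (H_ij / H_{5/6,j})`,

   from k random equal subgroups per tenth within each stratum j (D = cases,
   H = controls), giving replicate ORs, a mean and a 95% t-interval per
   tenth — the *PRS-factor*.
2. **Stability.** Per tenth, a one-way ANOVA compares replicate ORs between
   the entire cohort and strata defined by risk factors or by clinical risk
   categories, with Benjamini–Hochberg FDR across the eight tenths. A
   stable factor (all q > 0.05) means relative genetic risk does not depend
   on the clinical background.
3. **Independence.** Logistic models `Y ~ G + C (+ G:C)` with AIC selection
   test for gene-by-clinical interaction on the odds scale.
4. **Integration.** If stable and independent, total risk is simply
   multiplicative: `total risk = SCORE2 × PRS-factor` (capped at 1). The
   package quantifies the consequences by three-category risk
   reclassification (low / intermediate / high), Harrell's C on censored
   incident events, and the categorical net reclassification improvement
   (NRI), with individual-level bootstrap intervals.

A synthetic-cohort generator produces data with exactly the structure this
analysis assumes — approximately normal PRS, configurable CVD prevalence
(default 6.36%), a logistic outcome model multiplicative in genetic and
clinical components, an optional interaction term, and censored incident
event times — so the entire pipeline is testable without any data access.

## Worked example

```python
import pandas as pd
from prsfactor import (SimParams, simulate_cohort, PRSFactorModel,
                       compute_total_risk, compare_models)

cohort = simulate_cohort(SimParams(n_individuals=50_000, seed=1)).cohort
res = PRSFactorModel(
    cohort,
    strata={"smoking": cohort.smoking.astype(bool),
            "diabetes": cohort.diabetes.astype(bool)},
    clinical_categories="category",
    seed=1,
).fit()
print(res.summary())
```

```
PRS-factor (mean CVD OR vs merged 5/6 reference)

           mean_or  ci_low  ci_high  n_replicates
prs_group
1           0.6116  0.5122   0.7111            10
2           0.7864  0.6716   0.9013            10
3           0.8197  0.7189   0.9205            10
4           0.8778  0.7409   1.0148            10
5/6         1.0000     NaN      NaN             0
7           1.1708  0.9784   1.3633            10
8           1.2461  1.0210   1.4711            10
9           1.4854  1.3032   1.6675            10
10          1.7539  1.5650   1.9428            10

Stability ANOVA vs clinical_categories (df between = 3)
           sum_sq  mean_sq  f_value  p_value   fdr_q
prs_group
1          0.3147   0.1049   2.8773   0.0603  0.4322
...
```

The factor rises from 0.61 in the lowest tenth to 1.75 in the highest (a
~2.9-fold gradient of relative genetic risk), and no tenth shows a
significant OR difference across clinical risk categories (all FDR q >
0.05) — the stability that justifies multiplying it onto the clinical risk.

```python
free = cohort[cohort.prevalent_cvd == 0].copy()
total = compute_total_risk(free.score2_risk, free.prs_group,
                           res.factor_table, free.age)
free = pd.concat([free, total.drop(columns=["score2_risk"])], axis=1)
print(compare_models(free, bootstrap_b=200, seed=1).summary())
```

```
C-index clinical risk : 0.6737
C-index total risk    : 0.6923
delta C               : +0.0187
categorical NRI       : +0.1035 (events +0.1485, non-events -0.0450)
NRI bootstrap mean    : +0.1030 (95% CI +0.0807 to +0.1205, B=200)
```

The multiplicative model improves discrimination (ΔC > 0) and reclassifies
in the informative direction (NRI > 0): people moved from intermediate to
high risk go on to have markedly higher event rates than those who stay.

There is also a CLI mirroring the library
(`prsfactor simulate|prs|score2|factor|interact|reclassify|compare|pipeline`);
`prsfactor pipeline --seed 1 --n 50000 --out run/` reproduces the above
from the shell.

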