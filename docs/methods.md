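# Methods

## The model

The package treats cardiovascular risk as the product of two components:

* an **absolute clinical risk** `s ∈ (0,1)` — the 10-year probability of a
  first CVD event from a guideline tool (SCORE2 here; any externally
  computed risk column can be substituted); and
* a **relative genetic risk** — the odds ratio of the individual's PRS
  tenth against the merged fifth/sixth tenths (the *PRS-factor*), a step
  function of the PRS with the reference fixed at 1.

Multiplying the two (`total = s × factor`, capped at 1) is justified
exactly when (a) the per-tenth ORs are the same in every clinical stratum
(stability) and (b) genetic and clinical effects do not interact on the
odds scale (independence). Both conditions are testable, and the package
ships the tests alongside the model.

### PRS computation

`PRS_j = Σ_i S_i G_ij` with per-allele weights `S_i` (PGS-Catalog-style
scoring files) and dosages `G_ij ∈ [0,2]`. Missing dosages are imputed by
their Hardy–Weinberg expectation `2 × raf_i`; a variant with missing
dosages and no reference allele frequency is an error, never silently
skipped. Allele harmonization is deliberately minimal: weights and
genotypes are matched by variant id; swapped effect/other alleles flip the
dosage (`2 − d`); any other combination is an error. Strand guessing is
out of scope. QC order: monomorphic variants (observed allele frequency 0
or 1) → variant missing rate > 0.05 → Hardy–Weinberg χ² (1 df) p < 1e−6 →
sample missing rate > 0.02, recomputed on the retained variants. The HWE
test is the 1-df goodness-of-fit χ² standard in GWAS QC at these
thresholds; monomorphic input returns p = 1 by convention.

Scores are standardized on the analysis cohort itself (the tenths are
defined by the cohort's own distribution) using the sample SD (ddof 1).
Decile assignment is a stable sort on (value, input index), so tied scores
are resolved deterministically; group sizes differ by at most one.

### Replicate odds ratios and stability

Within stratum j, the members of each tenth i (and of the merged
reference) are randomly permuted (seeded) and split into k near-equal
subgroups; subgroup r of tenth i is paired with subgroup r of the
reference, and `OR_ijr = (D/D_ref)/(H/H_ref)` — algebraically the
cross-product ratio of the 2×2 table. Defaults: k = 10 for the entire
cohort and risk-factor strata, k = 5 for clinical risk categories (whose
smallest category would otherwise yield unusably small cells). Zero cells
get the Haldane–Anscombe +0.5 correction on all four cells, with a flag.
Random (rather than ordered) splitting gives exchangeable replicates for
the ANOVA; the seed is part of the run configuration.

The per-tenth PRS-factor is the mean replicate OR with a 95% t-interval
across replicates (the estimator is labelled as such; replicate ORs are
right-skewed and a log-OR option exists, but the plain OR scale is the
default reporting scale). The stability test is a one-way fixed-effects
ANOVA per tenth with groups {entire cohort, stratum₁, …}, computed from
explicit sums of squares (and cross-checked against `scipy.stats.f_oneway`
in the tests), followed by Benjamini–Hochberg FDR across the eight
non-reference tenths — one FDR family per stratification analysis.
Comparing the entire cohort with three clinical categories gives 3 between-
group degrees of freedom. The subgroups are subsets of the entire cohort,
which makes the test mildly conservative under the null; that is
acceptable for a stability screen.

### Interaction models

`InteractionModel` fits maximum-likelihood logistic regressions
`Y ~ G + C` and `Y ~ G + C + G:C` (optionally with a `C²` main-effect
term, since the clinical spectrum may act nonlinearly) and flags the
lowest-AIC fit. G can be the decile index (matching how a factor-style
genetic covariate is usually reported) or the standardized PRS; C can be a
risk-factor indicator, a clinical risk score, or its logit. Separation or
non-finite estimates raise a named error rather than returning garbage.

### Integration metrics

* Reclassification: full 3×3 origin-by-destination cross-tab over the
  initially event-free, with per-cell n, percent of origin, incident rate
  and risk-factor prevalences, plus derived shares (movers as a share of
  origin, inflow relative to the destination's original size, movers'
  versus stayers' incidence ratio) and a Sankey link list.
* Harrell's C via lifelines on censored incident times (pairs whose
  shorter time is censored are unusable; score ties count ½), checked
  against a brute-force all-pairs oracle. The Cox fit uses Efron tie
  handling with a tightened Newton precision (1e−12) so that the estimate
  agrees with a direct partial-likelihood maximization to 1e−6.
* Categorical NRI on the low/intermediate/high scale:
  `[P(up|event) − P(down|event)] + [P(down|non-event) − P(up|non-event)]`,
  on observed incident indicators within the follow-up horizon. A
  continuous NRI is deliberately not implemented.
* Bootstrap: individual-level resampling with replacement, percentile
  2.5/97.5 interval, seeded; default B = 1000 in the run configuration.

The factor applied to an individual is their tenth's mean OR — a step
function, exactly the construct being tested, not a smoothed curve. The
`upgrade_only` flag replaces factors below 1 by 1 (the counselling
convention of never downgrading a clinically derived risk); it defaults to
off so that analyses see the full reclassification including downgrades.

## SCORE2 engine

The risk engine is coefficient-agnostic. For linear predictor x built from
centred/scaled age, SBP, total and HDL cholesterol, smoking, and their
age-interaction terms (sex-specific weights):

    uncalibrated = 1 − S0^exp(x)
    calibrated   = 1 − exp(−exp(scale1 + scale2·ln(−ln(1 − uncalibrated))))

The shipped YAML carries the published sex-specific coefficients, baseline
survivals and low-risk-region recalibration scales of the SCORE2 model;
the published model parameterizes cholesterol as total + HDL terms, which
jointly encode the non-HDL signal. Other regions or scores plug in as
alternative files, and an externally computed risk column bypasses the
engine entirely. Medication adjustment (SBP +15 mmHg for treated blood
pressure, total cholesterol ÷ 0.8 for statin users) uses widely applied
conventions; the constants are configuration, not model logic, and should
be overridden when a cohort-specific calibration exists. Friedewald LDL
(`total − HDL − TG/2.2`, mmol/L) is flagged missing above 4.52 mmol/L
triglycerides.

Risk categories follow the ESC guideline age bands: <50 years 2.5%/7.5%,
50–69 years 5%/10%, boundary values assigned upward (consistent with "≥"
guideline thresholds).

## Synthetic cohort generator

The generator emulates the *assumed structure* of the analysis, not any
particular cohort:

* Variants: allele frequencies uniform on [0.05, 0.95], zero-mean normal
  weights, independent Binomial(2, f) dosages (Hardy–Weinberg by
  construction), uniform missingness. The PRS can also be drawn directly
  from its normal limiting distribution — statistically equivalent
  downstream and much faster; both modes are first-class.
* Covariates: age uniform on 40–69; SBP normal with a mild positive age
  slope (0.4 mmHg/year); lipids and BMI normal (triglycerides log-normal);
  binary smoking/diabetes/medication flags. Default fractions (smoking
  10.3%, diabetes 7.4%, male 45.2%, SBP 138 ± 18 mmHg) are chosen as
  realistic mid-life European-cohort values; the generator makes no claim
  of matching any real cohort's joint distribution beyond the calibrated
  prevalence and the configurability of the marginals.
* Outcomes: `logit(p) = α + w·logit(s) + ln(OR_sd)·z + γ·z·logit(s)` with
  the intercept α solved by monotone bisection (Brent) so that mean(p)
  equals the target prevalence (default 0.0636) to within 1e−6. Prevalent
  disease is Bernoulli(p). Among the initially disease-free, incident
  times are exponential with the constant hazard implied by p as a 10-year
  probability (`λ = −ln(1−p)/10`), censored administratively at the
  10-year horizon and by an independent exponential censoring process
  (rate 0.01/year). With γ = 0 the model is exactly multiplicative on the
  odds scale — the property the stability analysis is designed to detect.
* The default OR per SD of PRS (1.37) was calibrated once, by seeded
  simulation at n = 300 000, so that the top tenth carries a full-sample
  OR of ≈ 1.7 against the merged reference — the magnitude scale at which
  such factors are typically reported. It lives in `SimParams`, not in
  analysis code.

What passing tests on this generator do **not** show: robustness to linkage
disequilibrium, population structure, relatedness, age-dependent hazards,
informative censoring, or covariate correlation structures of real
cohorts — all deliberately absent from the generator (see Non-goals below).

## Numerical and design choices

* Prevalence bisection brackets α in [−50, 50]; an unbracketable target
  (degenerate parameters) is an error.
* ANOVA with zero within-group variance returns F = 0, p = 1 when the
  between-group variance is also zero.
* Weight-table round trips are byte-stable ("%g" float formatting).
* All randomness flows through `numpy.random.Generator` seeded by
  `SeedSequence([seed, salt])` with distinct salts per stage, so a single
  seed makes the full pipeline reproducible bit-for-bit.
* Problem sizes used by the test-suite's end-to-end checks: 20 seeded runs
  at n = 100 000 for stability, directionality and null-interaction
  coverage; single runs at n = 100 000 for calibration and interaction
  recovery. These sizes give per-replicate OR cells of ~10–100 cases even
  in the smallest clinical category, which is the regime the replicate
  ANOVA needs.

## Known limitations

* The stability ANOVA treats replicate ORs as exchangeable and roughly
  homoscedastic across groups; strata of very different sizes violate this
  mildly (larger strata have tighter replicate ORs).
* QRISK3 and other clinical scores are supported only as precomputed risk
  columns; no non-SCORE2 engine is implemented.
* The categorical NRI ignores censoring within the horizon (it uses the
  observed incident indicator); the C-index handles censoring properly.
* Chart-style (lookup-table) SCORE2 evaluation is not implemented; the
  continuous model is exact and is used throughout.
* HWE testing is the 1-df chi-square only (no exact test); the bootstrap
  resamples individuals without stratifying by event status; the applied
  factor is always the per-tenth step function (no interpolation). These
  were judged the right defaults for the analysis and kept singular rather
  than configurable.
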