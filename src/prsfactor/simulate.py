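"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: an
approximately normal polygenic score built from independent Hardy-Weinberg
genotypes, clinical covariates with configurable marginals, and CVD outcomes
from a logistic model whose genetic and clinical components are
multiplicative on the odds scale, with an optional gene-by-clinical
interaction term:

    logit(p_i) = alpha + w * logit(score2_i) + ln(OR_sd) * z_i
                 + gamma * z_i * logit(score2_i)

The intercept alpha is solved by bisection so the mean of p_i equals the
target prevalence to within 1e-6. Prevalent disease is Bernoulli(p_i);
among the initially disease-free, an incident event time is exponential
with the constant hazard implied by treating p_i as a 10-year probability,
censored administratively at the follow-up horizon and by an independent
exponential censoring process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import SimParams
from . import genetics, score2 as score2_mod


def _rng(params_seed: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params_seed, salt]))


def simulate_variants(params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant annotation and weight table for a desk-scale score.

    Allele frequencies are uniform on [0.05, 0.95]; per-allele weights are
    zero-mean normal with SD ``params.weight_sd``; the weight table's raf
    column carries the simulated frequency (used for missing-dosage
    imputation downstream).
    """
    if params.n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = _rng(params.seed, 1)
    m = params.n_variants
    freq = rng.uniform(0.05, 0.95, size=m)
    weight = rng.normal(0.0, params.weight_sd, size=m)
    alleles = np.array(list("ACGT"))
    eff = rng.integers(0, 4, size=m)
    oth = (eff + rng.integers(1, 4, size=m)) % 4
    variant_info = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(m)],
            "effect_allele": alleles[eff],
            "other_allele": alleles[oth],
            "freq": freq,
        }
    )
    weights = pd.DataFrame(
        {
            "variant_id": variant_info["variant_id"],
            "effect_allele": variant_info["effect_allele"],
            "other_allele": variant_info["other_allele"],
            "weight": weight,
            "raf": freq,
        }
    )
    return variant_info, weights


def simulate_genotypes(
    variant_info: pd.DataFrame, params: SimParams
) -> genetics.GenotypeMatrix:
    """Independent Binomial(2, raf) dosages with uniform missingness."""
    if len(variant_info) == 0:
        raise ValueError("variant_info is empty")
    rng = _rng(params.seed, 2)
    n, m = params.n_individuals, len(variant_info)
    freq = variant_info["freq"].to_numpy(float)
    dosage = rng.binomial(2, freq, size=(n, m)).astype(float)
    if params.missing_rate > 0:
        miss = rng.random(size=(n, m)) < params.missing_rate
        dosage[miss] = np.nan
    sample_ids = [f"id{i + 1}" for i in range(n)]
    return genetics.GenotypeMatrix(dosage, sample_ids,
                                   variant_info["variant_id"].tolist())


def simulate_covariates(params: SimParams) -> pd.DataFrame:
    """Clinical covariates with the configured marginal distributions.

    Age is uniform on the configured range; SBP is normal around a mean with
    a mild positive age slope; lipids and BMI are normal (triglycerides
    log-normal, and HDL floored at 0.3 mmol/L to keep lipid arithmetic
    valid); smoking, diabetes and medication flags are Bernoulli.
    """
    if params.n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    cov = params.covariates
    rng = _rng(params.seed, 3)
    n = params.n_individuals
    age = rng.uniform(cov.age_min, cov.age_max, size=n)
    sex = (rng.random(n) < cov.male_fraction).astype(int)
    sbp = rng.normal(cov.sbp_mean + cov.sbp_age_slope * (age - 55.0),
                     cov.sbp_sd)
    total_chol = np.maximum(rng.normal(cov.total_chol_mean, cov.total_chol_sd, n), 1.5)
    hdl = np.maximum(rng.normal(cov.hdl_mean, cov.hdl_sd, n), 0.3)
    tg = rng.lognormal(cov.triglycerides_logmean, cov.triglycerides_logsd, n)
    bmi = np.maximum(rng.normal(cov.bmi_mean, cov.bmi_sd, n), 14.0)
    df = pd.DataFrame(
        {
            "individual_id": [f"id{i + 1}" for i in range(n)],
            "sex": sex,
            "age": age,
            "sbp": sbp,
            "total_chol": total_chol,
            "hdl": hdl,
            "triglycerides": tg,
            "bmi": bmi,
            "smoking": (rng.random(n) < cov.smoking_fraction).astype(int),
            "diabetes": (rng.random(n) < cov.diabetes_fraction).astype(int),
            "bp_med": (rng.random(n) < cov.bp_med_fraction).astype(int),
            "lipid_med": (rng.random(n) < cov.lipid_med_fraction).astype(int),
        }
    ).set_index("individual_id")
    return df


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Solve mean(expit(alpha + eta)) = target by monotone bisection."""
    def f(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta))) - target

    lo, hi = -50.0, 50.0
    if not (f(lo) < 0 < f(hi)):
        raise ValueError("cannot bracket the prevalence intercept; "
                         "degenerate simulation parameters")
    return float(brentq(f, lo, hi, xtol=1e-12))


def simulate_outcomes(
    cohort: pd.DataFrame,
    zprs: np.ndarray | pd.Series,
    score2_risk: np.ndarray | pd.Series,
    params: SimParams,
) -> pd.DataFrame:
    """Attach prevalent/incident CVD status and censored follow-up times."""
    z = np.asarray(zprs, dtype=float)
    s2 = np.asarray(score2_risk, dtype=float)
    if np.any((s2 <= 0) | (s2 >= 1)):
        raise ValueError("score2_risk must lie in (0, 1)")
    lc = logit(s2)
    eta = (
        params.clinical_weight * lc
        + np.log(params.or_per_sd_prs) * z
        + params.interaction_gamma * z * lc
    )
    alpha = _calibrate_intercept(eta, params.target_prevalence)
    p = expit(alpha + eta)

    rng = _rng(params.seed, 4)
    prevalent = rng.random(len(p)) < p

    # constant hazard implied by p as a 10-year event probability
    lam = -np.log1p(-p) / 10.0
    t_event = rng.exponential(1.0 / lam)
    horizon = params.followup_horizon_years
    if params.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / params.censoring_rate, size=len(p))
    else:
        t_cens = np.full(len(p), np.inf)
    t_cens = np.minimum(t_cens, horizon)
    incident = (~prevalent) & (t_event <= t_cens)
    followup = np.where(prevalent, 0.0, np.minimum(t_event, t_cens))

    out = cohort.copy()
    out["prs_z"] = z
    out["score2_risk"] = s2
    out["p_outcome"] = p
    out["prevalent_cvd"] = prevalent.astype(int)
    out["incident_cvd"] = incident.astype(int)
    out["followup_years"] = followup
    return out


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    cohort: pd.DataFrame
    params: SimParams
    variant_info: pd.DataFrame | None = None
    weights: pd.DataFrame | None = None
    genotypes: genetics.GenotypeMatrix | None = None


def simulate_cohort(
    params: SimParams,
    with_genotypes: bool = False,
    coefficients: score2_mod.Score2Coefficients | None = None,
) -> SimulatedCohort:
    """End-to-end cohort: covariates, clinical risk, PRS, groups, outcomes.

    With ``with_genotypes`` the polygenic score is built from simulated
    variants/dosages through :func:`genetics.compute_prs`; otherwise the raw
    score is drawn directly from its (normal) limiting distribution, which is
    much faster and statistically equivalent for downstream analyses.
    """
    cov = simulate_covariates(params)
    risk = score2_mod.compute_score2(cov, coefficients)

    variant_info = weights = geno = None
    if with_genotypes:
        variant_info, weights = simulate_variants(params)
        geno = simulate_genotypes(variant_info, params)
        prs_raw = genetics.compute_prs(geno, weights)
        prs_raw.index = cov.index
    else:
        rng = _rng(params.seed, 5)
        prs_raw = pd.Series(rng.normal(size=len(cov)), index=cov.index,
                            name="prs_raw")
    groups = genetics.assign_prs_groups(prs_raw)

    cohort = simulate_outcomes(cov, groups["prs_z"], risk, params)
    cohort["prs_raw"] = groups["prs_raw"]
    cohort["prs_group"] = groups["prs_group"]
    cohort["is_reference"] = groups["is_reference"]
    cohort["category"] = score2_mod.categorize_risk(cohort["score2_risk"],
                                                    cohort["age"])
    return SimulatedCohort(cohort=cohort, params=params,
                           variant_info=variant_info, weights=weights,
                           genotypes=geno)
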