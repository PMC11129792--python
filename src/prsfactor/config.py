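"""Run configuration and simulation parameters.

All tunable knobs of the pipeline live here as plain dataclasses so a run is
fully described by one :class:`RunConfig` (loadable from YAML) plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class QCThresholds:
    """Genotype quality-control thresholds.

    Variants failing the Hardy-Weinberg test below ``hwe_p_min``, variants
    with missing rate above ``variant_missing_max`` and samples with missing
    rate above ``sample_missing_max`` are removed.
    """

    hwe_p_min: float = 1e-6
    variant_missing_max: float = 0.05
    sample_missing_max: float = 0.02

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "variant_missing_max", "sample_missing_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class CovariateParams:
    """Marginal distributions for the simulated clinical covariates.

    Units: age in years, SBP in mmHg, lipids in mmol/L, BMI in kg/m^2.
    Fractions are Bernoulli probabilities. SBP gets a mild positive age
    slope (mmHg per year, centred at age 55).
    """

    age_min: float = 40.0
    age_max: float = 69.0
    male_fraction: float = 0.452
    sbp_mean: float = 138.0
    sbp_sd: float = 18.0
    sbp_age_slope: float = 0.4
    total_chol_mean: float = 5.9
    total_chol_sd: float = 1.1
    hdl_mean: float = 1.45
    hdl_sd: float = 0.35
    triglycerides_logmean: float = 0.4
    triglycerides_logsd: float = 0.45
    bmi_mean: float = 27.4
    bmi_sd: float = 4.8
    smoking_fraction: float = 0.103
    diabetes_fraction: float = 0.074
    bp_med_fraction: float = 0.20
    lipid_med_fraction: float = 0.17

    def __post_init__(self) -> None:
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")
        for name in ("sbp_sd", "total_chol_sd", "hdl_sd", "bmi_sd",
                     "triglycerides_logsd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("male_fraction", "smoking_fraction", "diabetes_fraction",
                     "bp_med_fraction", "lipid_med_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimParams:
    """Parameters of the synthetic cohort generator.

    ``target_prevalence`` is the population CVD prevalence the outcome model
    is calibrated to. ``or_per_sd_prs`` is the odds ratio per standard
    deviation of the polygenic score; the default is calibrated so that the
    top PRS tenth carries an odds ratio of about 1.7 against the merged
    fifth/sixth tenths. ``clinical_weight`` scales the logit of the 10-year
    clinical risk; ``interaction_gamma`` is the coefficient on
    zPRS x logit(clinical risk) and is 0 under the purely multiplicative
    (odds-scale) model.
    """

    n_individuals: int = 10_000
    n_variants: int = 200
    seed: int = 0
    target_prevalence: float = 0.0636
    or_per_sd_prs: float = 1.37
    clinical_weight: float = 1.0
    interaction_gamma: float = 0.0
    missing_rate: float = 0.02
    weight_sd: float = 0.05
    followup_horizon_years: float = 10.0
    censoring_rate: float = 0.01
    covariates: CovariateParams = field(default_factory=CovariateParams)

    def __post_init__(self) -> None:
        if isinstance(self.covariates, dict):
            self.covariates = CovariateParams(**self.covariates)
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0, 1)")
        if self.or_per_sd_prs <= 0:
            raise ValueError("or_per_sd_prs must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.weight_sd <= 0:
            raise ValueError("weight_sd must be positive")
        if self.followup_horizon_years <= 0:
            raise ValueError("followup_horizon_years must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")


@dataclass
class ReplicateCounts:
    """Number of equal random subgroups used for replicate odds ratios.

    Each PRS tenth within a stratum is split into this many subgroups; one
    odds ratio is computed per subgroup against the matched reference split.
    """

    risk_factor_strata: int = 10
    clinical_categories: int = 5

    def __post_init__(self) -> None:
        if self.risk_factor_strata < 2 or self.clinical_categories < 2:
            raise ValueError("replicate counts must be >= 2")


@dataclass
class RunConfig:
    """Top-level configuration of a pipeline run."""

    seed: int = 0
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    score2_coefficients: Optional[str] = None  # path; None -> shipped file
    category_thresholds: Optional[dict] = None  # None -> guideline defaults
    replicate_counts: ReplicateCounts = field(default_factory=ReplicateCounts)
    bootstrap_reps: int = 1000
    upgrade_only: bool = False
    sim: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        if isinstance(self.qc_thresholds, dict):
            self.qc_thresholds = QCThresholds(**self.qc_thresholds)
        if isinstance(self.replicate_counts, dict):
            self.replicate_counts = ReplicateCounts(**self.replicate_counts)
        if isinstance(self.sim, dict):
            self.sim = SimParams(**self.sim)
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
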