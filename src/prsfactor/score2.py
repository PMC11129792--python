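"""Absolute 10-year CVD risk (SCORE2 model structure) and risk categories.

The engine is coefficient-agnostic: the sex-specific transformations,
log-hazard-ratio weights, baseline survival and region recalibration pair
are loaded from a YAML file (a low-risk-region set from the SCORE2
publication ships with the package). For an individual with linear
predictor x,

    uncalibrated risk = 1 - S0 ** exp(x)
    calibrated risk   = 1 - exp(-exp(scale1 + scale2 * ln(-ln(1 - uncalibrated))))

Risk categories follow the ESC guideline age bands: below age 50 the
low/intermediate and intermediate/high cut-offs are 2.5% and 7.5%; from 50
to 69 they are 5% and 10%. A boundary value belongs to the higher category.

Externally computed clinical risk (e.g. QRISK3) plugs in as a plain risk
column; nothing downstream depends on how the absolute risk was produced.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CATEGORIES = ("low", "intermediate", "high")

#: (low/intermediate, intermediate/high) cut-offs per age band, as fractions.
DEFAULT_CATEGORY_THRESHOLDS = {
    "under_50": (0.025, 0.075),
    "50_to_69": (0.05, 0.10),
}


@dataclass
class Score2Coefficients:
    """Sex-specific coefficient sets plus predictor transformations."""

    transformations: dict
    male: dict
    female: dict
    provenance: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "Score2Coefficients":
        """Load from a YAML file; with no path, load the shipped set."""
        if path is None:
            ref = importlib.resources.files("prsfactor.data").joinpath(
                "score2_coefficients.yaml"
            )
            raw = yaml.safe_load(ref.read_text())
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        for sex in ("male", "female"):
            if sex not in raw:
                raise ValueError(f"coefficient file lacks a '{sex}' block")
            s0 = raw[sex]["baseline_survival"]
            if not 0 < s0 < 1:
                raise ValueError(f"baseline survival must be in (0, 1), got {s0}")
        return cls(
            transformations=raw["transformations"],
            male=raw["male"],
            female=raw["female"],
            provenance=raw.get("provenance", ""),
        )


def adjust_for_medication(
    cohort: pd.DataFrame,
    sbp_offset: float = 15.0,
    total_chol_factor: float = 0.8,
) -> pd.DataFrame:
    """Undo treatment effects on measured SBP and total cholesterol.

    Individuals on blood-pressure medication get ``sbp_offset`` mmHg added to
    their SBP; individuals on lipid-lowering medication get total cholesterol
    divided by ``total_chol_factor``. Untreated rows are unchanged. The
    defaults are widely used conventions, not values fixed by the model, and
    should be overridden where a cohort-specific calibration exists.
    """
    out = cohort.copy()
    bp = out["bp_med"].astype(bool)
    lip = out["lipid_med"].astype(bool)
    out.loc[bp, "sbp"] = out.loc[bp, "sbp"] + sbp_offset
    out.loc[lip, "total_chol"] = out.loc[lip, "total_chol"] / total_chol_factor
    if (out["sbp"] < 0).any() or (out["total_chol"] < 0).any():
        raise ValueError("medication adjustment produced negative values")
    return out


FRIEDEWALD_TG_LIMIT = 4.52  # mmol/L; Friedewald LDL invalid above this


def derive_lipids(
    total_chol, hdl, triglycerides, tg_limit: float = FRIEDEWALD_TG_LIMIT
):
    """Non-HDL cholesterol and Friedewald LDL (mmol/L).

    non-HDL = total - HDL; LDL = total - HDL - TG/2.2. LDL is flagged
    missing (NaN) where triglycerides exceed the validity bound.
    """
    total_chol = np.asarray(total_chol, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(triglycerides, dtype=float)
    if np.any(total_chol <= 0) or np.any(hdl <= 0) or np.any(tg <= 0):
        raise ValueError("lipid inputs must be positive (mmol/L)")
    non_hdl = total_chol - hdl
    ldl = total_chol - hdl - tg / 2.2
    ldl = np.where(tg > tg_limit, np.nan, ldl)
    return non_hdl, ldl


def _sex_linear_predictor(df: pd.DataFrame, coeffs: Score2Coefficients,
                          block: dict) -> np.ndarray:
    t = coeffs.transformations
    cage = (df["age"].to_numpy(float) - t["age"]["center"]) / t["age"]["scale"]
    csbp = (df["sbp"].to_numpy(float) - t["sbp"]["center"]) / t["sbp"]["scale"]
    ctc = (df["total_chol"].to_numpy(float) - t["total_chol"]["center"]) \
        / t["total_chol"]["scale"]
    chdl = (df["hdl"].to_numpy(float) - t["hdl"]["center"]) / t["hdl"]["scale"]
    smoke = df["smoking"].to_numpy(float)
    c = block["coefficients"]
    x = (
        c["age"] * cage
        + c["smoking"] * smoke
        + c["sbp"] * csbp
        + c["total_chol"] * ctc
        + c["hdl"] * chdl
        + c["smoking_age"] * smoke * cage
        + c["sbp_age"] * csbp * cage
        + c["total_chol_age"] * ctc * cage
        + c["hdl_age"] * chdl * cage
    )
    return x


def compute_score2(
    cohort: pd.DataFrame,
    coeffs: Score2Coefficients | None = None,
    age_range: tuple[float, float] = (40.0, 69.0),
    clamp_age: bool = False,
) -> pd.Series:
    """Calibrated 10-year first-onset CVD risk per individual.

    Requires columns ``sex`` (1 = male, 0 = female), ``age``, ``sbp``,
    ``total_chol``, ``hdl``, ``smoking``. Ages outside ``age_range`` raise
    unless ``clamp_age`` truncates them to the range.
    """
    coeffs = coeffs or Score2Coefficients.from_yaml()
    df = cohort.copy()
    age = df["age"].to_numpy(float)
    lo, hi = age_range
    if clamp_age:
        df["age"] = np.clip(age, lo, hi)
    elif np.any((age < lo) | (age > hi)):
        bad = age[(age < lo) | (age > hi)][0]
        raise ValueError(f"age {bad} outside model range [{lo}, {hi}]")

    male = df["sex"].astype(int).to_numpy() == 1
    x = np.empty(len(df), dtype=float)
    x[male] = _sex_linear_predictor(df.loc[male], coeffs, coeffs.male)
    x[~male] = _sex_linear_predictor(df.loc[~male], coeffs, coeffs.female)

    risk = np.empty(len(df), dtype=float)
    for mask, block in ((male, coeffs.male), (~male, coeffs.female)):
        s0 = block["baseline_survival"]
        uncal = 1.0 - s0 ** np.exp(x[mask])
        cloglog = np.log(-np.log(1.0 - uncal))
        risk[mask] = 1.0 - np.exp(
            -np.exp(block["scale1"] + block["scale2"] * cloglog)
        )
    return pd.Series(risk, index=cohort.index, name="score2_risk")


def categorize_risk(
    risk, age, thresholds: dict | None = None
) -> pd.Series:
    """Map absolute risk to low / intermediate / high given age.

    ``thresholds`` maps the two age bands to ascending (cut1, cut2) pairs of
    risk fractions; a value equal to a cut-off goes to the higher category.
    """
    thresholds = thresholds or DEFAULT_CATEGORY_THRESHOLDS
    for band, (c1, c2) in thresholds.items():
        if not c1 < c2:
            raise ValueError(f"thresholds for {band} must be ascending")
    index = risk.index if isinstance(risk, pd.Series) else None
    risk = np.asarray(risk, dtype=float)
    age = np.asarray(age, dtype=float)
    c1 = np.where(age < 50, thresholds["under_50"][0], thresholds["50_to_69"][0])
    c2 = np.where(age < 50, thresholds["under_50"][1], thresholds["50_to_69"][1])
    cat = np.where(risk >= c2, "high", np.where(risk >= c1, "intermediate", "low"))
    return pd.Series(pd.Categorical(cat, categories=list(CATEGORIES), ordered=True),
                     index=index, name="category")
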