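"""Gene-by-clinical interaction models with AIC selection.

Logistic models of the binary CVD outcome on a genetic term G (PRS tenth
index or standardized PRS) and a clinical term C (a risk-factor indicator,
a clinical risk score, or its logit), optionally with covariates (e.g.
principal components). The candidate set contains the main-effects model
and the model adding the G:C product term (and, optionally, a squared-C
term in both); the fit with the lowest AIC is flagged as selected. If the
multiplicative (odds-scale) decomposition of risk holds, the interaction
coefficient is zero and AIC favours the main-effects model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


class SeparationError(RuntimeError):
    """Raised when a logistic fit fails to produce finite estimates."""


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> sm.Logit:
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    bad = ~np.isfinite(res.params) | ~np.isfinite(res.bse)
    if bad.any():
        term = X.columns[np.argmax(bad.to_numpy() if hasattr(bad, "to_numpy") else bad)]
        raise SeparationError(f"non-finite estimate for term '{term}'")
    return res


def _param_table(res) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "beta": res.params,
            "std_error": res.bse,
            "z_value": res.tvalues,
            "p_value": res.pvalues,
        }
    )


@dataclass
class InteractionFit:
    """One candidate model: term table, AIC and selection flag."""

    name: str
    terms: list
    params: pd.DataFrame
    aic: float
    selected: bool = False


class InteractionModel:
    """Test independence of genetic and clinical effects on CVD risk.

    Parameters
    ----------
    cohort:
        Table containing the outcome, genetic and clinical columns.
    outcome:
        Binary outcome column name.
    genetic:
        Column name for G (e.g. ``prs_group`` index or ``prs_z``).
    clinical:
        Column name for C (risk-factor indicator or clinical risk score).
    covariates:
        Additional adjustment columns entered linearly in every candidate.
    include_squared:
        Add a C^2 main-effect term to every candidate model.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        outcome: str,
        genetic: str,
        clinical: str,
        covariates: list[str] | None = None,
        include_squared: bool = False,
    ):
        self.data = cohort
        self.outcome = outcome
        self.genetic = genetic
        self.clinical = clinical
        self.covariates = list(covariates or [])
        self.include_squared = include_squared

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "InteractionModel":
        return cls(cohort, **kwargs)

    def _design(self, with_interaction: bool) -> pd.DataFrame:
        g = self.data[self.genetic].to_numpy(dtype=float)
        c = self.data[self.clinical].to_numpy(dtype=float)
        cols = {"const": np.ones(len(g)), self.genetic: g, self.clinical: c}
        if self.include_squared:
            cols[f"{self.clinical}^2"] = c**2
        for cov in self.covariates:
            cols[cov] = self.data[cov].to_numpy(dtype=float)
        if with_interaction:
            cols[self.interaction_term] = g * c
        return pd.DataFrame(cols, index=self.data.index)

    @property
    def interaction_term(self) -> str:
        return f"{self.genetic}:{self.clinical}"

    def fit(self) -> "InteractionResults":
        y = self.data[self.outcome].to_numpy(dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        fits = []
        for name, with_int in (("main_effects", False), ("interaction", True)):
            X = self._design(with_int)
            res = _fit_logit(y, X)
            fits.append(
                InteractionFit(
                    name=name,
                    terms=list(X.columns),
                    params=_param_table(res),
                    aic=float(res.aic),
                )
            )
        best = int(np.argmin([f.aic for f in fits]))
        fits[best].selected = True
        return InteractionResults(model=self, fits=fits)


@dataclass
class InteractionResults:
    """Candidate fits, the AIC-selected model and the interaction row."""

    model: InteractionModel
    fits: list = field(default_factory=list)

    @property
    def selected(self) -> InteractionFit:
        return next(f for f in self.fits if f.selected)

    @property
    def interaction_fit(self) -> InteractionFit:
        return next(f for f in self.fits if f.name == "interaction")

    @property
    def interaction_row(self) -> pd.Series:
        """Beta/SE/z/p of the G:C term from the interaction model."""
        return self.interaction_fit.params.loc[self.model.interaction_term]

    def interaction_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        row = self.interaction_row
        zq = norm.ppf(0.5 + level / 2)
        return (row["beta"] - zq * row["std_error"],
                row["beta"] + zq * row["std_error"])

    def summary(self) -> str:
        lines = []
        for f in self.fits:
            mark = " (selected by AIC)" if f.selected else ""
            lines.append(f"Model '{f.name}', AIC = {f.aic:.2f}{mark}")
            lines.append(f.params.round(4).to_string())
            lines.append("")
        return "\n".join(lines)
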