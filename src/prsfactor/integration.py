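"""Multiplicative total risk, reclassification and model comparison.

Total risk is the product of the absolute 10-year clinical risk and the
individual's relative genetic risk (the mean OR of their PRS tenth):

    total risk = clinical risk x PRS-factor      (capped at 1)

Reclassification cross-tabulates the clinical risk categories before and
after applying the factor, with per-cell incidence among the initially
event-free and risk-factor prevalences. Model performance is compared by
Harrell's C on censored incident events (Cox models via lifelines, Efron
ties) and by the categorical net reclassification improvement, with
individual-level bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index as _lifelines_cindex

from .score2 import CATEGORIES, categorize_risk

_CAT_RANK = {c: r for r, c in enumerate(CATEGORIES)}


def compute_total_risk(
    score2_risk,
    prs_group,
    factor_table: pd.DataFrame,
    age,
    cap: float = 1.0,
    upgrade_only: bool = False,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Apply the per-tenth factor to clinical risk and re-categorize.

    ``factor_table`` is the PRS-factor table indexed by tenth label (the
    merged reference row '5/6' carries factor 1). With ``upgrade_only`` a
    factor below 1 is replaced by 1 (the counselling convention of never
    downgrading a clinically derived risk).
    """
    from .genetics import group_label

    s2 = np.asarray(score2_risk, dtype=float)
    grp = np.asarray(prs_group, dtype=int)
    labels = [group_label(g) for g in grp]
    missing = sorted({l for l in labels if l not in factor_table.index})
    if missing:
        raise ValueError(f"factor table lacks PRS tenths {missing}")
    factor = factor_table["mean_or"].loc[labels].to_numpy(dtype=float)
    if upgrade_only:
        factor = np.maximum(factor, 1.0)
    total = np.minimum(s2 * factor, cap)
    original = categorize_risk(s2, age, thresholds)
    new = categorize_risk(total, age, thresholds)
    return pd.DataFrame(
        {
            "score2_risk": s2,
            "prs_factor": factor,
            "total_risk": total,
            "original_category": original.to_numpy(),
            "new_category": new.to_numpy(),
        },
        index=score2_risk.index if isinstance(score2_risk, pd.Series) else None,
    )


@dataclass
class ReclassificationTable:
    """Origin x destination reclassification counts with per-cell summaries.

    ``table`` holds one row per (origin, destination) cell: ``n``,
    ``pct_of_origin``, ``incidence_pct`` among the initially event-free, and
    the prevalence (percent) of each tracked risk factor.
    """

    table: pd.DataFrame
    risk_factor_cols: list = field(default_factory=list)

    @classmethod
    def from_cohort(
        cls,
        original_category: Sequence,
        new_category: Sequence,
        incident: Sequence,
        risk_factors: pd.DataFrame | None = None,
    ) -> "ReclassificationTable":
        """Build the full cross-tab from per-individual assignments.

        All inputs must already be restricted to participants free of CVD at
        baseline (incidence is only defined for them).
        """
        orig = pd.Categorical(original_category, categories=list(CATEGORIES))
        new = pd.Categorical(new_category, categories=list(CATEGORIES))
        inc = np.asarray(incident, dtype=float)
        rf_cols = list(risk_factors.columns) if risk_factors is not None else []
        rows = []
        for o in CATEGORIES:
            o_mask = np.asarray(orig == o)
            o_total = int(o_mask.sum())
            for dcat in CATEGORIES:
                mask = o_mask & np.asarray(new == dcat)
                n = int(mask.sum())
                row = {
                    "origin": o,
                    "destination": dcat,
                    "n": n,
                    "pct_of_origin": 100.0 * n / o_total if o_total else np.nan,
                    "incidence_pct": 100.0 * inc[mask].mean() if n else np.nan,
                }
                for col in rf_cols:
                    vals = risk_factors[col].to_numpy(dtype=float)[mask]
                    row[f"{col}_pct"] = 100.0 * vals.mean() if n else np.nan
                rows.append(row)
        return cls(pd.DataFrame(rows), risk_factor_cols=rf_cols)

    @classmethod
    def from_counts(cls, table: pd.DataFrame) -> "ReclassificationTable":
        """Wrap a pre-tabulated cell table (columns origin, destination, n,
        optionally incidence_pct and prevalence columns); fills
        ``pct_of_origin`` from the counts."""
        tab = table.copy()
        totals = tab.groupby("origin", observed=False)["n"].transform("sum")
        tab["pct_of_origin"] = 100.0 * tab["n"] / totals
        rf = [c[:-4] for c in tab.columns
              if c.endswith("_pct") and c not in ("pct_of_origin", "incidence_pct")]
        return cls(tab, risk_factor_cols=rf)

    def _cell(self, origin: str, destination: str) -> pd.Series:
        m = (self.table["origin"] == origin) & (self.table["destination"] == destination)
        if not m.any():
            raise KeyError(f"cell {origin}->{destination} absent")
        return self.table.loc[m].iloc[0]

    def origin_total(self, origin: str) -> int:
        return int(self.table.loc[self.table["origin"] == origin, "n"].sum())

    def moved_share_pct(self, origin: str, destination: str) -> float:
        """Percent of the origin category reclassified to the destination."""
        return 100.0 * self._cell(origin, destination)["n"] / self.origin_total(origin)

    def relative_inflow_pct(self, origin: str, destination: str) -> float:
        """Movers origin->destination as a percent of the destination's
        original size (e.g. the growth of the high-risk group from
        intermediate-risk upgrades)."""
        return 100.0 * self._cell(origin, destination)["n"] / self.origin_total(destination)

    def incidence_ratio(self, origin: str, destination: str) -> float:
        """Incidence among movers relative to those staying in the origin."""
        moved = self._cell(origin, destination)["incidence_pct"]
        stayed = self._cell(origin, origin)["incidence_pct"]
        return float(moved / stayed)

    def max_jump(self) -> int:
        """Largest number of category steps any occupied cell represents."""
        occ = self.table.loc[self.table["n"] > 0]
        return int(
            max(
                abs(_CAT_RANK[r["origin"]] - _CAT_RANK[r["destination"]])
                for _, r in occ.iterrows()
            )
        )

    def summary(self) -> str:
        return self.table.round(2).to_string(index=False)


def export_sankey(reclass: ReclassificationTable) -> pd.DataFrame:
    """Link list (source, target, count, incidence_pct) for Sankey plots.

    Only occupied cells appear; counts are conserved (they sum to the
    event-free cohort size).
    """
    tab = reclass.table
    links = tab.loc[tab["n"] > 0, ["origin", "destination", "n", "incidence_pct"]]
    links = links.rename(
        columns={"origin": "source", "destination": "target", "n": "count"}
    )
    return links.reset_index(drop=True)


def fit_cox(time, event, score) -> tuple[float, float]:
    """Single-covariate Cox partial-likelihood fit (Efron tie handling).

    Returns (log hazard ratio, standard error).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time <= 0):
        raise ValueError("event/censoring times must be positive")
    if event.sum() == 0:
        raise ValueError("no events observed")
    df = pd.DataFrame({"time": time, "event": event,
                       "score": np.asarray(score, dtype=float)})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-12})
    except Exception as exc:
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    return float(cph.params_["score"]), float(cph.standard_errors_["score"])


def concordance_index(time, event, score) -> float:
    """Harrell's C for a risk score against censored event times.

    Higher score is expected to mean earlier events; a pair whose shorter
    time is censored is unusable; ties in score count one half.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    score = np.asarray(score, dtype=float)
    return float(_lifelines_cindex(time, -score, event))


def categorical_nri(old_category, new_category, event) -> dict:
    """Categorical net reclassification improvement and its components.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)]
    on the ordered low/intermediate/high scale.
    """
    old = pd.Categorical(old_category, categories=list(CATEGORIES))
    new = pd.Categorical(new_category, categories=list(CATEGORIES))
    ev = np.asarray(event, dtype=bool)
    if ev.sum() == 0 or (~ev).sum() == 0:
        raise ValueError("need both events and non-events for the NRI")
    old_r = np.asarray(old.codes)
    new_r = np.asarray(new.codes)
    if np.any(old_r < 0) or np.any(new_r < 0):
        raise ValueError("categories outside the low/intermediate/high scale")
    up = new_r > old_r
    down = new_r < old_r
    ev_comp = up[ev].mean() - down[ev].mean()
    ne_comp = down[~ev].mean() - up[~ev].mean()
    return {
        "nri": float(ev_comp + ne_comp),
        "event_component": float(ev_comp),
        "nonevent_component": float(ne_comp),
    }


def bootstrap_metric(
    metric: Callable[[pd.DataFrame], float],
    data: pd.DataFrame,
    b: int = 1000,
    seed: int = 0,
    max_retries: int = 10,
) -> dict:
    """Individual-level bootstrap mean and 2.5/97.5 percentile interval."""
    if b < 1:
        raise ValueError("b must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    n = len(data)
    values = np.empty(b, dtype=float)
    for i in range(b):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            try:
                values[i] = metric(data.iloc[idx])
                break
            except Exception:
                if attempt == max_retries:
                    raise RuntimeError(
                        f"metric failed on {max_retries + 1} consecutive "
                        f"bootstrap resamples"
                    )
    return {
        "mean": float(values.mean()),
        "ci_low": float(np.percentile(values, 2.5)),
        "ci_high": float(np.percentile(values, 97.5)),
        "b": b,
    }


@dataclass
class ModelComparison:
    """C-index and categorical NRI comparing clinical vs total risk."""

    c_index_clinical: float
    c_index_total: float
    delta_c: float
    nri: dict
    nri_bootstrap: dict | None = None

    def summary(self) -> str:
        lines = [
            f"C-index clinical risk : {self.c_index_clinical:.4f}",
            f"C-index total risk    : {self.c_index_total:.4f}",
            f"delta C               : {self.delta_c:+.4f}",
            f"categorical NRI       : {self.nri['nri']:+.4f} "
            f"(events {self.nri['event_component']:+.4f}, "
            f"non-events {self.nri['nonevent_component']:+.4f})",
        ]
        if self.nri_bootstrap:
            lines.append(
                f"NRI bootstrap mean    : {self.nri_bootstrap['mean']:+.4f} "
                f"(95% CI {self.nri_bootstrap['ci_low']:+.4f} to "
                f"{self.nri_bootstrap['ci_high']:+.4f}, "
                f"B={self.nri_bootstrap['b']})"
            )
        return "\n".join(lines)


def compare_models(
    df: pd.DataFrame,
    time_col: str = "followup_years",
    event_col: str = "incident_cvd",
    clinical_col: str = "score2_risk",
    total_col: str = "total_risk",
    old_cat_col: str = "original_category",
    new_cat_col: str = "new_category",
    bootstrap_b: int = 0,
    seed: int = 0,
) -> ModelComparison:
    """Compare clinical-only and multiplicative total-risk models.

    ``df`` must be restricted to participants free of CVD at baseline.
    With ``bootstrap_b`` > 0 the NRI additionally gets a bootstrap mean and
    percentile interval.
    """
    c_clin = concordance_index(df[time_col], df[event_col], df[clinical_col])
    c_tot = concordance_index(df[time_col], df[event_col], df[total_col])
    nri = categorical_nri(df[old_cat_col], df[new_cat_col], df[event_col])
    boot = None
    if bootstrap_b > 0:
        boot = bootstrap_metric(
            lambda d: categorical_nri(d[old_cat_col], d[new_cat_col],
                                      d[event_col])["nri"],
            df, b=bootstrap_b, seed=seed,
        )
    return ModelComparison(
        c_index_clinical=c_clin,
        c_index_total=c_tot,
        delta_c=c_tot - c_clin,
        nri=nri,
        nri_bootstrap=boot,
    )
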