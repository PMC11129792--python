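"""Decile-wise relative genetic risk (the PRS-factor) and its stability.

For PRS tenth *i* within stratum *j* (the entire cohort, a risk-factor
subgroup, or a clinical risk category), members are split at random into k
equal subgroups, and each subgroup's CVD odds ratio is computed against the
matched subgroup of the merged fifth/sixth-tenth reference in the same
stratum:

    OR_ij = (D_ij / D_{5/6,j}) / (H_ij / H_{5/6,j})

with D case counts and H control counts. The replicate ORs give a mean and
t-interval per tenth (the PRS-factor table), and a one-way ANOVA per tenth
compares mean ORs between the entire cohort and the strata; Benjamini-
Hochberg FDR adjustment is applied across the eight non-reference tenths.
A stable (multiplicative) genetic effect shows no significant differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetics import REFERENCE_GROUPS, REFERENCE_LABEL, group_label

NON_REFERENCE_GROUPS = (1, 2, 3, 4, 7, 8, 9, 10)


@dataclass
class ORPoint:
    value: float
    corrected: bool = False

    def __float__(self) -> float:
        return self.value


def or_point(d: float, h: float, d_ref: float, h_ref: float) -> ORPoint:
    """Ratio-of-proportions odds ratio against the reference subgroup.

    Algebraically identical to the cross-product ratio of the 2x2 table.
    If any cell is zero, 0.5 is added to all four cells (Haldane-Anscombe)
    and the result is flagged as corrected.
    """
    cells = np.array([d, h, d_ref, h_ref], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    if d_ref + h_ref == 0:
        raise ValueError("empty reference subgroup")
    if np.all(cells == 0):
        raise ValueError("all cells are zero")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    d, h, d_ref, h_ref = cells
    return ORPoint((d / d_ref) / (h / h_ref), corrected)


def _split_replicates(index: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(index)
    return np.array_split(perm, k)


def or_replicates(
    groups: pd.DataFrame,
    stratum: str,
    mask: np.ndarray | pd.Series | None,
    k: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Replicate odds ratios for every non-reference tenth within a stratum.

    ``groups`` needs columns ``prs_group`` (1-10) and ``case`` (bool/0-1);
    ``mask`` selects the stratum members (None = everyone). Members of each
    tenth (and of the merged reference) are randomly permuted and split into
    ``k`` near-equal subgroups; replicate r of tenth i is paired with
    replicate r of the reference.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sub = groups if mask is None else groups.loc[np.asarray(mask, dtype=bool)]
    case = sub["case"].to_numpy(dtype=bool)
    grp = sub["prs_group"].to_numpy(dtype=int)

    ref_idx = np.flatnonzero(np.isin(grp, REFERENCE_GROUPS))
    if len(ref_idx) < k:
        raise ValueError(
            f"reference group has {len(ref_idx)} members in stratum "
            f"'{stratum}', fewer than k={k}; use a smaller k"
        )
    ref_splits = _split_replicates(ref_idx, k, rng)
    ref_counts = [(int(case[s].sum()), int((~case[s]).sum())) for s in ref_splits]

    rows = []
    for g in NON_REFERENCE_GROUPS:
        g_idx = np.flatnonzero(grp == g)
        if len(g_idx) < k:
            raise ValueError(
                f"PRS group {g} has {len(g_idx)} members in stratum "
                f"'{stratum}', fewer than k={k}; use a smaller k"
            )
        for r, split in enumerate(_split_replicates(g_idx, k, rng)):
            d = int(case[split].sum())
            h = int((~case[split]).sum())
            d_ref, h_ref = ref_counts[r]
            pt = or_point(d, h, d_ref, h_ref)
            rows.append(
                {
                    "stratum": stratum, "prs_group": g, "replicate": r,
                    "d": d, "h": h, "d_ref": d_ref, "h_ref": h_ref,
                    "odds_ratio": pt.value, "corrected": pt.corrected,
                }
            )
    return pd.DataFrame(rows)


def estimate_prs_factor(replicates: pd.DataFrame) -> pd.DataFrame:
    """Mean OR and 95% t-interval per tenth from entire-cohort replicates.

    The merged reference tenths are emitted with OR 1 and an empty interval.
    """
    present = set(replicates["prs_group"].unique())
    missing = [g for g in NON_REFERENCE_GROUPS if g not in present]
    if missing:
        raise ValueError(f"replicates missing for PRS tenths {missing}")
    rows = []
    for g in (1, 2, 3, 4, 5, 7, 8, 9, 10):  # 5 stands for the merged 5/6 row
        if g == 5:
            rows.append({"prs_group": REFERENCE_LABEL, "mean_or": 1.0,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "n_replicates": 0})
            continue
        ors = replicates.loc[replicates["prs_group"] == g, "odds_ratio"]
        n = len(ors)
        m = float(ors.mean())
        if n > 1 and ors.std(ddof=1) > 0:
            half = float(stats.t.ppf(0.975, n - 1) * ors.std(ddof=1) / np.sqrt(n))
        else:
            half = 0.0
        rows.append({"prs_group": str(g), "mean_or": m, "ci_low": m - half,
                     "ci_high": m + half, "n_replicates": n})
    return pd.DataFrame(rows).set_index("prs_group")


def factor_gradient(factor_table: pd.DataFrame) -> float:
    """Fold-change of relative genetic risk from the top to the bottom tenth."""
    return float(factor_table.loc["10", "mean_or"] / factor_table.loc["1", "mean_or"])


def anova_oneway(groups: Sequence[np.ndarray]) -> dict:
    """One-way fixed-effects ANOVA from explicit sums of squares.

    Returns between-group sum of squares, mean square, F, p and the degrees
    of freedom. Identical groups yield F = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every ANOVA group needs at least 2 replicates")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_between = len(arrays) - 1
    df_within = len(all_vals) - len(arrays)
    ms_between = ss_between / df_between
    if ss_within == 0:
        f_val, p = (0.0, 1.0) if ss_between == 0 else (np.inf, 0.0)
    else:
        ms_within = ss_within / df_within
        f_val = ms_between / ms_within
        p = float(stats.f.sf(f_val, df_between, df_within))
    return {
        "sum_sq": ss_between, "mean_sq": ms_between, "f_value": float(f_val),
        "p_value": float(p), "df_between": df_between, "df_within": df_within,
    }


def anova_stability(
    entire: pd.DataFrame, strata: Mapping[str, pd.DataFrame],
    scale: str = "or",
) -> pd.DataFrame:
    """Per-tenth ANOVA of replicate ORs: entire cohort vs each stratum.

    ``entire`` and every value of ``strata`` are replicate tables from
    :func:`or_replicates`. Returns one row per non-reference tenth with the
    ANOVA block and a Benjamini-Hochberg q value across the eight tenths.
    ``scale`` is ``"or"`` (the reporting scale) or ``"log"`` (replicate ORs
    are right-skewed; the log scale symmetrizes them).
    """
    if scale not in ("or", "log"):
        raise ValueError("scale must be 'or' or 'log'")
    transform = np.log if scale == "log" else np.asarray
    rows = []
    for g in NON_REFERENCE_GROUPS:
        arrays = [transform(
            entire.loc[entire["prs_group"] == g, "odds_ratio"].to_numpy()
        )]
        for name, rep in strata.items():
            arrays.append(transform(
                rep.loc[rep["prs_group"] == g, "odds_ratio"].to_numpy()
            ))
        res = anova_oneway(arrays)
        res["prs_group"] = g
        rows.append(res)
    out = pd.DataFrame(rows).set_index("prs_group")
    out["fdr_q"] = fdr_adjust(out["p_value"].to_numpy())
    return out


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


class PRSFactorModel:
    """Estimate the PRS-factor and test its stability across strata.

    Parameters
    ----------
    cohort:
        Per-individual table with a binary ``outcome`` column and a
        ``prs_group`` column (1-10).
    outcome:
        Name of the binary case/control column (default ``prevalent_cvd``).
    strata:
        Mapping of stratum name to a boolean mask/column name selecting the
        risk-factor subgroup (e.g. smokers, diabetics).
    clinical_categories:
        Name of a categorical clinical-risk column; each level becomes a
        stratum in a second stability analysis with its own replicate count.
    k_strata, k_categories:
        Replicate subgroup counts for risk-factor strata (default 10, also
        used for the entire cohort) and clinical categories (default 5).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        outcome: str = "prevalent_cvd",
        prs_group_col: str = "prs_group",
        strata: Mapping[str, object] | None = None,
        clinical_categories: str | None = None,
        k_strata: int = 10,
        k_categories: int = 5,
        anova_scale: str = "or",
        seed: int = 0,
    ):
        self.data = cohort
        self.outcome = outcome
        self.prs_group_col = prs_group_col
        self.strata = dict(strata or {})
        self.clinical_categories = clinical_categories
        self.k_strata = k_strata
        self.k_categories = k_categories
        self.anova_scale = anova_scale
        self.seed = seed

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "PRSFactorModel":
        return cls(cohort, **kwargs)

    def _mask(self, selector) -> np.ndarray:
        if isinstance(selector, str):
            return self.data[selector].to_numpy(dtype=bool)
        return np.asarray(selector, dtype=bool)

    def fit(self) -> "PRSFactorResults":
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 11]))
        groups = pd.DataFrame(
            {
                "prs_group": self.data[self.prs_group_col].to_numpy(dtype=int),
                "case": self.data[self.outcome].to_numpy(dtype=bool),
            }
        )
        entire = or_replicates(groups, "entire", None, self.k_strata, rng)
        factor_table = estimate_prs_factor(entire)

        replicates = [entire]
        strata_reps: dict[str, pd.DataFrame] = {}
        for name, selector in self.strata.items():
            rep = or_replicates(groups, name, self._mask(selector),
                                self.k_strata, rng)
            strata_reps[name] = rep
            replicates.append(rep)

        category_reps: dict[str, pd.DataFrame] = {}
        if self.clinical_categories is not None:
            cats = self.data[self.clinical_categories]
            for level in cats.cat.categories if hasattr(cats, "cat") else sorted(cats.unique()):
                mask = (cats == level).to_numpy()
                rep = or_replicates(groups, f"category:{level}", mask,
                                    self.k_categories, rng)
                category_reps[str(level)] = rep
                replicates.append(rep)

        stability = {}
        if strata_reps:
            stability["risk_factors"] = anova_stability(
                entire, strata_reps, scale=self.anova_scale)
        if category_reps:
            stability["clinical_categories"] = anova_stability(
                entire, category_reps, scale=self.anova_scale)

        return PRSFactorResults(
            model=self,
            factor_table=factor_table,
            replicates=pd.concat(replicates, ignore_index=True),
            stability=stability,
        )


@dataclass
class PRSFactorResults:
    """Fitted PRS-factor table, replicate ORs and stability tests."""

    model: PRSFactorModel
    factor_table: pd.DataFrame
    replicates: pd.DataFrame
    stability: dict = field(default_factory=dict)

    def factor_for(self, prs_group: int) -> float:
        """The multiplicative factor applied to an individual of this tenth."""
        return float(self.factor_table.loc[group_label(int(prs_group)), "mean_or"])

    def gradient(self) -> float:
        return factor_gradient(self.factor_table)

    def stable_tenths(self, analysis: str, alpha: float = 0.05) -> int:
        """Number of tenths whose stability ANOVA has FDR q above alpha."""
        return int((self.stability[analysis]["fdr_q"] > alpha).sum())

    def summary(self) -> str:
        lines = ["PRS-factor (mean CVD OR vs merged 5/6 reference)", ""]
        lines.append(self.factor_table.round(4).to_string())
        for name, tab in self.stability.items():
            lines.append("")
            lines.append(f"Stability ANOVA vs {name} "
                         f"(df between = {int(tab['df_between'].iloc[0])})")
            lines.append(
                tab[["sum_sq", "mean_sq", "f_value", "p_value", "fdr_q"]]
                .round(4).to_string()
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Mean OR with CI per PRS tenth (reference fixed at 1)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.factor_table
        x = np.arange(len(tab))
        err_lo = tab["mean_or"] - tab["ci_low"].fillna(tab["mean_or"])
        err_hi = tab["ci_high"].fillna(tab["mean_or"]) - tab["mean_or"]
        ax.errorbar(x, tab["mean_or"], yerr=[err_lo, err_hi], fmt="o",
                    capsize=3)
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xticks(x, tab.index)
        ax.set_xlabel("PRS tenth")
        ax.set_ylabel("CVD odds ratio vs 5/6 reference")
        return ax
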