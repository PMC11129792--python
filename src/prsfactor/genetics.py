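"""Genotype QC, additive polygenic score computation and decile assignment.

The polygenic risk score of individual *j* is the additive model

    PRS_j = sum_i S_i * G_ij

where ``S_i`` is the per-allele weight of variant *i* and ``G_ij`` in
{0, 1, 2} (or a dosage in [0, 2]) counts the effect alleles. A missing
dosage is replaced by its Hardy-Weinberg expectation, twice the reference
risk-allele frequency. Scores are standardized on the analysis cohort and
individuals are ranked into ten equal groups; the merged fifth/sixth tenths
serve as the genetic reference group (odds ratio fixed at 1 downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import QCThresholds

REFERENCE_GROUPS = (5, 6)
REFERENCE_LABEL = "5/6"


class GenotypeMatrix:
    """Individuals x variants dosage matrix with missing entries as NaN.

    Dosages are real values in [0, 2]; ``sample_ids`` and ``variant_ids``
    index rows and columns respectively.
    """

    def __init__(self, dosage: np.ndarray, sample_ids, variant_ids):
        dosage = np.asarray(dosage, dtype=float)
        if dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D array")
        sample_ids = list(sample_ids)
        variant_ids = list(variant_ids)
        if dosage.shape != (len(sample_ids), len(variant_ids)):
            raise ValueError(
                f"dosage shape {dosage.shape} inconsistent with "
                f"{len(sample_ids)} samples x {len(variant_ids)} variants"
            )
        if len(set(variant_ids)) != len(variant_ids):
            raise ValueError("duplicate variant ids")
        with np.errstate(invalid="ignore"):
            bad = (dosage < 0) | (dosage > 2)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage out of range [0, 2]: {dosage[i, j]} at sample "
                f"{sample_ids[i]}, variant {variant_ids[j]}"
            )
        self.dosage = dosage
        self.sample_ids = sample_ids
        self.variant_ids = variant_ids

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def variant_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """Hard-call genotype counts per variant: columns (hom-ref, het, hom-alt).

        Dosages are rounded to the nearest integer; missing entries ignored.
        """
        counts = np.zeros((self.n_variants, 3), dtype=int)
        rounded = np.round(self.dosage)
        for g in (0, 1, 2):
            counts[:, g] = np.nansum(rounded == g, axis=0)
        return counts

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeMatrix":
        d = self.dosage
        sids, vids = self.sample_ids, self.variant_ids
        if variant_mask is not None:
            d = d[:, variant_mask]
            vids = [v for v, keep in zip(vids, variant_mask) if keep]
        if sample_mask is not None:
            d = d[sample_mask, :]
            sids = [s for s, keep in zip(sids, sample_mask) if keep]
        return GenotypeMatrix(d, sids, vids)


@dataclass
class QCReport:
    """Per-stage counts of removed variants and samples."""

    variants_in: int = 0
    samples_in: int = 0
    variants_dropped: dict = field(default_factory=dict)
    samples_dropped: dict = field(default_factory=dict)
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def variants_out(self) -> int:
        return self.variants_in - sum(self.variants_dropped.values())

    @property
    def samples_out(self) -> int:
        return self.samples_in - sum(self.samples_dropped.values())


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against Hardy-Weinberg.

    Expected genotype counts come from the sample allele frequency.
    A monomorphic variant returns p = 1 by convention.
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p_hat = (2 * n_hom_alt + n_het) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 1.0
    q_hat = 1 - p_hat
    expected = n * np.array([q_hat**2, 2 * p_hat * q_hat, p_hat**2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def apply_qc(
    geno: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter variants and samples in the standard order.

    Stages: monomorphic variants -> variant missing rate -> Hardy-Weinberg
    -> sample missing rate (recomputed on the retained variants).
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport(
        variants_in=geno.n_variants, samples_in=geno.n_samples,
        thresholds=thresholds,
    )

    # monomorphic: observed allele frequency 0 or 1
    with np.errstate(all="ignore"):
        freq = np.nanmean(geno.dosage, axis=0) / 2.0
    mono = ((freq == 0) | (freq == 1)) & ~np.all(np.isnan(geno.dosage), axis=0)
    report.variants_dropped["monomorphic"] = int(mono.sum())
    geno = geno.subset(variant_mask=~mono)

    vmiss = geno.variant_missing_rate() > thresholds.variant_missing_max
    report.variants_dropped["missing_rate"] = int(vmiss.sum())
    geno = geno.subset(variant_mask=~vmiss)

    counts = geno.genotype_counts()
    hwe_p = np.array([hwe_test(*row) for row in counts])
    hwe_fail = hwe_p < thresholds.hwe_p_min
    report.variants_dropped["hwe"] = int(hwe_fail.sum())
    geno = geno.subset(variant_mask=~hwe_fail)

    smiss = geno.sample_missing_rate() > thresholds.sample_missing_max
    report.samples_dropped["missing_rate"] = int(smiss.sum())
    geno = geno.subset(sample_mask=~smiss)

    return geno, report


def _harmonize_weights(
    weights: pd.DataFrame, variant_info: pd.DataFrame
) -> np.ndarray:
    """Return +1/-1 per variant: -1 flips the dosage (2 - d).

    Weights and genotypes are matched on variant id and effect allele. If the
    weight table's effect/other alleles are swapped relative to the genotype
    annotation the dosage is flipped; any other allele combination is an
    error (strand flips are out of scope and never guessed at).
    """
    vi = variant_info.set_index("variant_id")
    sign = np.ones(len(weights), dtype=float)
    for k, row in enumerate(weights.itertuples(index=False)):
        if row.variant_id not in vi.index:
            continue
        ref = vi.loc[row.variant_id]
        if row.effect_allele == ref["effect_allele"]:
            if "other_allele" in ref.index and \
                    getattr(row, "other_allele", ref["other_allele"]) != ref["other_allele"]:
                raise ValueError(
                    f"allele mismatch for {row.variant_id}: other allele "
                    f"{row.other_allele} vs {ref['other_allele']}"
                )
            sign[k] = 1.0
        elif (
            row.effect_allele == ref.get("other_allele")
            and getattr(row, "other_allele", None) == ref["effect_allele"]
        ):
            sign[k] = -1.0
        else:
            raise ValueError(
                f"allele mismatch for {row.variant_id}: weight table "
                f"{row.effect_allele}/{getattr(row, 'other_allele', '?')} vs "
                f"genotypes {ref['effect_allele']}/{ref.get('other_allele', '?')}"
            )
    return sign


def compute_prs(
    geno: GenotypeMatrix,
    weights: pd.DataFrame,
    variant_info: pd.DataFrame | None = None,
) -> pd.Series:
    """Additive PRS per individual, with the missing-dosage rule.

    Every genotyped variant must be present in the weight table. A missing
    dosage is imputed as 2 x raf (reference risk-allele frequency); a variant
    with missing dosages but no raf is an error. When ``variant_info``
    provides allele annotation, weight/genotype allele swaps flip the dosage.
    """
    w = weights.set_index("variant_id")
    missing_ids = [v for v in geno.variant_ids if v not in w.index]
    if missing_ids:
        raise ValueError(
            f"variants absent from weight table: {missing_ids[:5]}"
            + ("..." if len(missing_ids) > 5 else "")
        )
    w = w.loc[geno.variant_ids]
    dosage = geno.dosage
    if variant_info is not None:
        aligned = w.reset_index()
        sign = _harmonize_weights(aligned, variant_info)
        dosage = np.where(sign < 0, 2.0 - dosage, dosage)

    miss = np.isnan(dosage)
    if miss.any():
        if "raf" not in w.columns:
            j = int(np.flatnonzero(miss.any(axis=0))[0])
            raise ValueError(
                f"variant {geno.variant_ids[j]} has missing dosages and the "
                "weight table carries no raf column"
            )
        raf = w["raf"].to_numpy(dtype=float)
        needs = miss.any(axis=0)
        bad = needs & ~np.isfinite(raf)
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"variant {geno.variant_ids[j]} has missing dosages but no raf"
            )
        fill = np.broadcast_to(2.0 * raf, dosage.shape)
        dosage = np.where(miss, fill, dosage)

    prs = dosage @ w["weight"].to_numpy(dtype=float)
    return pd.Series(prs, index=pd.Index(geno.sample_ids, name="individual_id"),
                     name="prs_raw")


def assign_prs_groups(prs_raw: pd.Series) -> pd.DataFrame:
    """Standardize the PRS and rank individuals into ten equal groups.

    Group 1 holds the lowest scores; groups 5 and 6 are flagged as the merged
    reference. Ties are broken by stable input order, making the assignment
    reproducible. Group sizes differ by at most one.
    """
    n = len(prs_raw)
    if n < 10:
        raise ValueError(f"need at least 10 individuals to form tenths, got {n}")
    values = prs_raw.to_numpy(dtype=float)
    z = (values - values.mean()) / values.std(ddof=1)

    order = np.argsort(values, kind="stable")
    group = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(order, 10), start=1):
        group[chunk] = g

    out = pd.DataFrame(
        {
            "prs_raw": values,
            "prs_z": z,
            "prs_group": group,
            "is_reference": np.isin(group, REFERENCE_GROUPS),
        },
        index=prs_raw.index,
    )
    return out


def group_label(group: int) -> str:
    """Display label for a PRS tenth: the reference tenths merge to '5/6'."""
    return REFERENCE_LABEL if group in REFERENCE_GROUPS else str(group)
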