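"""Readers and writers for the external formats of the pipeline.

Weight tables follow the PGS-Catalog scoring-file column conventions
(rsID / effect_allele / other_allele / effect_weight, with
allelefrequency_effect accepted for the reference allele frequency).
Genotypes come either from VCF (GT or DS fields; multi-allelic records and
indels are dropped and counted) or from a plain variants x samples dosage
TSV. Cohort tables, result tables and the run summary are TSV/JSON.
All readers validate and reject rather than silently coerce.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import GenotypeMatrix
from .integration import ReclassificationTable

logger = logging.getLogger("prsfactor")

_VALID_ALLELES = set("ACGT")

#: accepted header aliases (PGS-Catalog names first) -> canonical name
_WEIGHT_ALIASES = {
    "rsid": "variant_id",
    "variant_id": "variant_id",
    "id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "reference_allele": "other_allele",
    "effect_weight": "weight",
    "weight": "weight",
    "allelefrequency_effect": "raf",
    "raf": "raf",
}

COHORT_REQUIRED = [
    "sex", "age", "sbp", "total_chol", "hdl", "smoking", "diabetes", "bmi",
    "bp_med", "lipid_med", "prevalent_cvd", "incident_cvd", "followup_years",
]


def read_weight_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated PRS weight table.

    Row order is preserved. Requires variant id, effect allele and weight
    columns; other allele and raf are optional (a missing raf makes missing
    dosages an error downstream).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cols = {}
    for c in raw.columns:
        key = c.strip().lower()
        if key in _WEIGHT_ALIASES:
            cols[c] = _WEIGHT_ALIASES[key]
    df = raw.rename(columns=cols)
    for required in ("variant_id", "effect_allele", "weight"):
        if required not in df.columns:
            raise ValueError(f"weight table lacks a '{required}' column")

    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate variant id: {dup.iloc[0]}")
    for col in ("effect_allele", "other_allele"):
        if col not in df.columns:
            continue
        bad = ~df[col].isin(_VALID_ALLELES)
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2  # header is line 1
            raise ValueError(
                f"non-allele character '{df[col][bad].iloc[0]}' in column "
                f"{col}, line {line}"
            )
    try:
        df["weight"] = df["weight"].astype(float)
    except ValueError as exc:
        raise ValueError(f"unparsable weight: {exc}") from exc
    if df["weight"].isna().any():
        raise ValueError("missing weight values")
    if "raf" in df.columns:
        df["raf"] = df["raf"].astype(float)
        out_of_range = ((df["raf"] < 0) | (df["raf"] > 1)) & df["raf"].notna()
        if out_of_range.any():
            raise ValueError("raf outside [0, 1]")
    keep = [c for c in ("variant_id", "effect_allele", "other_allele",
                        "weight", "raf") if c in df.columns]
    return df[keep]


def write_weight_table(weights: pd.DataFrame, path: str | Path) -> None:
    """Write a weight table using PGS-Catalog column names."""
    names = {"variant_id": "rsID", "effect_allele": "effect_allele",
             "other_allele": "other_allele", "weight": "effect_weight",
             "raf": "allelefrequency_effect"}
    out = weights.rename(columns=names)
    out.to_csv(path, sep="\t", index=False, float_format="%g")


def _is_biallelic_snv(ref: str, alts: list[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref in _VALID_ALLELES
        and alts[0] in _VALID_ALLELES
    )


def read_genotypes(
    path: str | Path, format: str = "vcf"
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read genotypes from VCF or a dosage TSV.

    Returns the dosage matrix plus a variant annotation table
    (variant_id, effect_allele = the counted ALT allele, other_allele).
    VCF records that are not biallelic SNVs are dropped with a logged count.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format '{format}'")


def _read_vcf(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages, records = [], []
    dropped = 0
    for var in vcf:
        if not _is_biallelic_snv(var.REF, var.ALT):
            dropped += 1
            continue
        fmt = var.FORMAT
        if "DS" in fmt:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            gts = var.genotype.array()
            alleles = np.asarray(gts[:, :2], dtype=float)
            alleles[alleles < 0] = np.nan
            ds = alleles.sum(axis=1)
        dosages.append(ds)
        vid = var.ID if var.ID not in (None, ".") else \
            f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        records.append((vid, var.ALT[0], var.REF))
    if dropped:
        logger.info("dropped %d non-biallelic-SNV records from %s",
                    dropped, path)
    dosage = np.array(dosages, dtype=float).T if dosages else \
        np.empty((len(samples), 0))
    info = pd.DataFrame(records,
                        columns=["variant_id", "effect_allele", "other_allele"])
    info.attrs["n_dropped"] = dropped
    return GenotypeMatrix(dosage, samples, info["variant_id"].tolist()), info


def _read_dosage_tsv(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    n_fields = df.shape[1]
    with open(path) as fh:
        header_n = len(fh.readline().rstrip("\n").split("\t")) - 1
    if header_n != n_fields:
        raise ValueError(
            f"sample-count mismatch: header names {header_n} samples, "
            f"rows carry {n_fields}"
        )
    dosage = df.to_numpy(dtype=float).T  # file is variants x samples
    with np.errstate(invalid="ignore"):
        if np.any((dosage < 0) | (dosage > 2)):
            raise ValueError("dosage out of range [0, 2]")
    info = pd.DataFrame({"variant_id": df.index.astype(str)})
    return GenotypeMatrix(dosage, list(df.columns), list(df.index.astype(str))), info


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.dosage.T, index=pd.Index(geno.variant_ids, name="variant_id"),
                      columns=geno.sample_ids)
    df.to_csv(path, sep="\t", float_format="%g", na_rep="NA")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-individual phenotype table (TSV).

    Extra columns are preserved. The first column is used as the individual
    id index when named ``individual_id``.
    """
    df = pd.read_csv(path, sep="\t")
    if "individual_id" in df.columns:
        df = df.set_index("individual_id")
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks required columns: {missing}")
    if (df["followup_years"] < 0).any():
        raise ValueError("negative follow-up time")
    return df


def write_cohort_table(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=cohort.index.name is not None)


def write_factor_table(factor_table: pd.DataFrame, path: str | Path) -> None:
    factor_table.to_csv(path, sep="\t")


def write_stability_table(stability: pd.DataFrame, path: str | Path) -> None:
    stability.to_csv(path, sep="\t")


def write_reclassification_table(
    reclass: ReclassificationTable, path: str | Path
) -> None:
    reclass.table.to_csv(path, sep="\t", index=False)


def read_reclassification_table(path: str | Path) -> ReclassificationTable:
    tab = pd.read_csv(path, sep="\t")
    return ReclassificationTable(tab, risk_factor_cols=[
        c[:-4] for c in tab.columns
        if c.endswith("_pct") and c not in ("pct_of_origin", "incidence_pct")
    ])


def write_sankey(links: pd.DataFrame, path: str | Path) -> None:
    links.to_csv(path, sep="\t", index=False)


def write_json_summary(summary: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_default)
        fh.write("\n")


def write_result_tables(results: dict, out_dir: str | Path) -> list[Path]:
    """Write every recognised result object into ``out_dir``.

    Recognised keys: ``factor_table``, ``stability`` (dict of tables),
    ``reclassification``, ``sankey``, ``summary``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "factor_table" in results:
        p = out_dir / "prs_factor.tsv"
        write_factor_table(results["factor_table"], p)
        written.append(p)
    for name, tab in (results.get("stability") or {}).items():
        p = out_dir / f"stability_{name}.tsv"
        write_stability_table(tab, p)
        written.append(p)
    if "reclassification" in results:
        p = out_dir / "reclassification.tsv"
        write_reclassification_table(results["reclassification"], p)
        written.append(p)
    if "sankey" in results:
        p = out_dir / "sankey.tsv"
        write_sankey(results["sankey"], p)
        written.append(p)
    if "summary" in results:
        p = out_dir / "summary.json"
        write_json_summary(results["summary"], p)
        written.append(p)
    return written
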