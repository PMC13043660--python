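"""Readers and writers for the standard formats the pipeline touches.

VCF 4.x for genotype dosages (DS FORMAT field preferred over GT when both
are present), tab-separated tables for cohorts and GWAS summary
statistics, PGS-Catalog-style scoring files, and JSON for ground-truth /
report payloads. Readers validate loudly: a malformed file fails with a
named error, never silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import GenotypeMatrix, VARIANT_COLUMNS

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["CHR", "POS", "ID", "A1", "BETA", "SE", "STAT", "P", "N"]


class SchemaError(ValueError):
    """A table is missing required columns or violates its schema."""


@dataclass
class PgsWeightRecord:
    variant_key: str  # rsID, or chrom:pos when no rsID column exists
    effect_allele: str
    effect_weight: float


# ---------------------------------------------------------------------- VCF

def write_vcf_dosages(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT (rounded dosage) and DS fields."""
    ids = genotypes.individual_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description='
                 '"Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, ids)) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in genotypes.variants.iterrows():
            fields = [str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                      str(row["ref"]), str(row["alt"]), ".", "PASS", ".",
                      "GT:DS"]
            col = genotypes.dosages[:, j]
            samples = []
            for d in col:
                if np.isnan(d):
                    samples.append("./.:.")
                else:
                    gt = gt_codes[int(np.clip(round(d), 0, 2))]
                    samples.append(f"{gt}:{d:.6g}")
            fh.write("\t".join(fields + samples) + "\n")


def read_vcf_dosages(path, id_filter=None) -> GenotypeMatrix:
    """Read biallelic dosages from a VCF.

    DS is preferred over GT when both are present; missing genotypes become
    NaN; multiallelic records are skipped with a warning. ``id_filter``
    optionally restricts to a set of variant IDs.
    """
    vcf = VCF(str(path), gts012=True)
    sample_ids = np.asarray(vcf.samples)
    rows = []
    dosage_rows = []
    n_skipped = 0
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) != 1:
            n_skipped += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if id_filter is not None and vid not in id_filter:
            continue
        ds = None
        try:
            ds_field = rec.format("DS")
        except KeyError:
            ds_field = None
        if ds_field is not None:
            ds = np.asarray(ds_field, dtype=float).reshape(-1)
            ds = np.where((ds < -0.5) | (ds > 2.5), np.nan, ds)
        else:
            gt = np.asarray(rec.gt_types, dtype=float)
            ds = np.where(gt == 3, np.nan, gt)
        rows.append({"chrom": rec.CHROM, "pos": rec.POS, "id": vid,
                     "ref": rec.REF, "alt": rec.ALT[0]})
        dosage_rows.append(ds)
    vcf.close()
    if n_skipped:
        logger.warning("skipped %d multiallelic record(s) in %s", n_skipped, path)
    if not rows:
        variants = pd.DataFrame(columns=VARIANT_COLUMNS)
        dosages = np.empty((len(sample_ids), 0))
    else:
        variants = pd.DataFrame(rows)[VARIANT_COLUMNS]
        dosages = np.column_stack(dosage_rows)
    return GenotypeMatrix(dosages=dosages, variants=variants,
                          individual_ids=sample_ids)


# -------------------------------------------------------------------- TSV

def write_table(df: pd.DataFrame, path, index_name: str = None) -> None:
    """Write a tab-separated table with a header row.

    Floats are written with 12 significant digits so a round trip is the
    identity to ~1e-12. A non-trivial index is written as the key column.
    """
    out = df
    if index_name is not None:
        out = df.reset_index().rename(columns={df.index.name or "index": index_name})
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path, schema: str = None, index_col: str = None) -> pd.DataFrame:
    """Read a tab-separated table with a header row.

    schema='cohort' requires an ``individual_id`` column (set as index);
    schema='sumstats' requires the CHR/POS/ID/A1/BETA/SE/P/N columns.
    Unparseable cells in numeric columns become missing, with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    if schema == "cohort":
        if "individual_id" not in df.columns:
            raise SchemaError("cohort table missing required column: individual_id")
        index_col = "individual_id"
        text_cols = {"individual_id"}
    elif schema == "sumstats":
        required = [c for c in ["CHR", "POS", "ID", "A1", "BETA", "SE", "P", "N"]
                    if c not in df.columns]
        if required:
            raise SchemaError(f"sumstats table missing required columns: {required}")
        text_cols = {"CHR", "ID", "A1"}
    else:
        text_cols = {index_col} if index_col else set()

    n_coerced = 0
    for col in df.columns:
        if col in text_cols:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        unparseable = converted.isna() & df[col].notna()
        if converted.notna().sum() == 0 and unparseable.any():
            continue  # genuinely textual column, leave as strings
        n_coerced += int(unparseable.sum())
        df[col] = converted
    if n_coerced:
        logger.warning("read_table: %d unparseable cell(s) set to missing in %s",
                       n_coerced, path)
    if index_col:
        df = df.set_index(index_col)
    return df


# -------------------------------------------------------- PGS weight files

def read_pgs_weights(path) -> list:
    """Parse a PGS-Catalog-style scoring file.

    Lines starting with '#' are metadata. Requires an ``effect_allele`` and
    ``effect_weight`` column plus either ``rsID`` or ``chr_name`` +
    ``chr_position``. Duplicate variant keys keep the first record.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "effect_weight" not in df.columns:
        raise SchemaError("scoring file has no effect_weight column")
    if "effect_allele" not in df.columns:
        raise SchemaError("scoring file has no effect_allele column")
    if "rsID" in df.columns:
        keys = df["rsID"]
    elif {"chr_name", "chr_position"}.issubset(df.columns):
        keys = df["chr_name"].astype(str) + ":" + df["chr_position"].astype(str)
    else:
        raise SchemaError("scoring file needs rsID or chr_name/chr_position")

    records = []
    seen = set()
    n_dup = 0
    for key, allele, weight in zip(keys, df["effect_allele"], df["effect_weight"]):
        if key in seen:
            n_dup += 1
            continue
        w = float(weight)
        if not np.isfinite(w):
            raise SchemaError(f"non-finite effect_weight for {key}")
        seen.add(key)
        records.append(PgsWeightRecord(variant_key=str(key),
                                       effect_allele=str(allele),
                                       effect_weight=w))
    if n_dup:
        logger.warning("read_pgs_weights: %d duplicate key(s) dropped (kept first)",
                       n_dup)
    return records


# ------------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def match_effect_allele(ref: str, alt: str, effect_allele: str):
    """Allele orientation for scoring.

    Returns 'alt' (use dosage), 'ref' (use 2 - dosage) or None (skip and
    log; strand flips are never guessed, silent strand guessing corrupts
    scores).
    """
    if effect_allele == alt:
        return "alt"
    if effect_allele == ref:
        return "ref"
    return None
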