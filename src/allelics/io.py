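"""Readers and writers for the package's on-disk formats.

Genotypes travel either as a minimal GT-only VCF (1-based positions, MAF
and imputation INFO score carried as INFO keys) or as a pair of TSVs
(samples x variants dosage matrix plus a variant-annotation sidecar).
Phenotypes, pulldown runs, Ct tables and truth labels are plain TSV with a
header row, UTF-8, '.' for missing.  Every writer/reader pair round-trips
bit-exactly on generated data.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from .binders import PulldownRun
from .containers import GenotypeMatrix

__all__ = [
    "ParseError",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_pulldown_run",
    "read_pulldown_run",
    "write_ct_table",
    "read_ct_table",
]

MISSING = "."


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotypes_vcf(G: GenotypeMatrix, path: str,
                        maf_key: str = "MAF", info_key: str = "INFO") -> None:
    """Write a minimal GT-only VCF (uncompressed text)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=allelics\n")
        for chrom in pd.unique(G.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f'##INFO=<ID={maf_key},Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write(f'##INFO=<ID={info_key},Number=1,Type=Float,Description="Imputation information score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        for j in range(G.n_variants):
            v = G.variants.iloc[j]
            info_parts = []
            if not np.isnan(v["maf"]):
                info_parts.append(f"{maf_key}={v['maf']:.10g}")
            if not np.isnan(v["info"]):
                info_parts.append(f"{info_key}={v['info']:.10g}")
            info = ";".join(info_parts) if info_parts else MISSING
            gts = "\t".join(
                _GT_CODE.get(G.genotypes[i, j], "./.") for i in range(G.n_samples)
            )
            fh.write(f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                     f"\t.\t.\t{info}\tGT\t{gts}\n")


def _precheck_vcf(path: str) -> int:
    """Light structural validation with line numbers; returns sample count."""
    n_fields = None
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise ParseError(f"{path}: line 1: missing ##fileformat header")
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 10:
                    raise ParseError(f"{path}: line {lineno}: header has no sample columns")
                n_fields = len(cols)
                continue
            if not line.strip():
                continue
            if n_fields is None:
                raise ParseError(f"{path}: line {lineno}: record before #CHROM header")
            got = len(line.rstrip("\n").split("\t"))
            if got != n_fields:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_fields} fields, found {got}"
                )
    if n_fields is None:
        raise ParseError(f"{path}: no #CHROM header line found")
    return n_fields - 9


def read_genotypes_vcf(path: str, maf_key: str = "MAF", info_key: str = "INFO") -> GenotypeMatrix:
    """Read a GT-only VCF into a :class:`GenotypeMatrix` (via cyvcf2)."""
    from cyvcf2 import VCF

    _precheck_vcf(path)
    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    records, columns = [], []
    for variant in vcf:
        if variant.ploidy != 2:
            raise ParseError(f"{path}: variant {variant.ID}: mixed or non-diploid ploidy")
        maf = variant.INFO.get(maf_key)
        info = variant.INFO.get(info_key)
        records.append(
            dict(id=variant.ID, chrom=variant.CHROM, pos=variant.POS,
                 ref=variant.REF, alt=variant.ALT[0] if variant.ALT else MISSING,
                 maf=np.nan if maf is None else float(maf),
                 info=np.nan if info is None else float(info))
        )
        # gts012: 0/1/2 = alt dosage, 3 = unknown
        g = variant.gt_types.astype(float)
        g[g == 3] = np.nan
        columns.append(g)
    geno = np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids, pd.DataFrame.from_records(records), geno)


# ---------------------------------------------------------------------------
# TSV genotype dialect
# ---------------------------------------------------------------------------

def write_genotypes_tsv(G: GenotypeMatrix, geno_path: str, variants_path: str) -> None:
    """Samples x variants dosage TSV plus a variant-annotation sidecar."""
    cols = {"sample_id": G.sample_ids}
    for j, vid in enumerate(G.variant_ids):
        cols[vid] = [MISSING if np.isnan(v) else str(int(v)) for v in G.genotypes[:, j]]
    pd.DataFrame(cols).to_csv(geno_path, sep="\t", index=False)
    G.variants.to_csv(variants_path, sep="\t", index=False, na_rep=MISSING)


def read_genotypes_tsv(geno_path: str, variants_path: str) -> GenotypeMatrix:
    try:
        mat = pd.read_csv(geno_path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # pandas messages carry line numbers
        raise ParseError(f"{geno_path}: {exc}") from exc
    if "sample_id" not in mat.columns:
        raise ParseError(f"{geno_path}: line 1: missing 'sample_id' column")
    sample_ids = mat["sample_id"].tolist()
    body = mat.drop(columns="sample_id")
    geno = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        for i, val in enumerate(body[col]):
            if val == MISSING or val != val:
                geno[i, j] = np.nan
            else:
                try:
                    geno[i, j] = float(val)
                except ValueError as exc:
                    raise ParseError(
                        f"{geno_path}: line {i + 2}: bad genotype {val!r} for {col!r}"
                    ) from exc
    variants = pd.read_csv(variants_path, sep="\t", na_values=[MISSING])
    variants["id"] = variants["id"].astype(str)
    return GenotypeMatrix(sample_ids, variants, geno)


def read_genotypes(path: str, variants_path: Optional[str] = None,
                   format_hint: Optional[str] = None) -> GenotypeMatrix:
    """Dispatch on format hint or file extension (.vcf vs .tsv)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format_hint or ("vcf" if path.endswith(".vcf") else "tsv")
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    if variants_path is None:
        raise ValueError("TSV genotypes need a variant-annotation sidecar path")
    return read_genotypes_tsv(path, variants_path)


# ---------------------------------------------------------------------------
# phenotypes / simple tables
# ---------------------------------------------------------------------------

def write_phenotypes(sample_ids, phenotype, path: str,
                     covariates: Optional[pd.DataFrame] = None) -> None:
    tbl = pd.DataFrame({"sample_id": list(sample_ids),
                        "phenotype": np.asarray(phenotype, dtype=int)})
    if covariates is not None:
        tbl = pd.concat([tbl, covariates.reset_index(drop=True)], axis=1)
    tbl.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_phenotypes(path: str) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t", na_values=[MISSING])
    if "sample_id" not in tbl.columns or "phenotype" not in tbl.columns:
        raise ParseError(f"{path}: line 1: need 'sample_id' and 'phenotype' columns")
    return tbl


def write_pulldown_run(run: PulldownRun, path: str) -> None:
    tbl = run.table.copy()
    tbl.insert(0, "run_id", run.run_id)
    tbl.insert(1, "orientation", run.orientation)
    tbl.insert(2, "competitor", run.competitor)
    tbl.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_pulldown_run(path: str) -> PulldownRun:
    tbl = pd.read_csv(path, sep="\t", na_values=[MISSING])
    for col in ("run_id", "orientation", "protein_id", "intensity_c", "intensity_g"):
        if col not in tbl.columns:
            raise ParseError(f"{path}: line 1: missing column {col!r}")
    run_id = str(tbl["run_id"].iloc[0])
    orientation = str(tbl["orientation"].iloc[0])
    competitor = str(tbl["competitor"].iloc[0]) if "competitor" in tbl.columns else "poly-dAdT"
    return PulldownRun(
        run_id=run_id, orientation=orientation,
        table=tbl[["protein_id", "intensity_c", "intensity_g"]].copy(),
        competitor=competitor,
    )


CT_COLUMNS = ["sample", "target", "allele", "condition", "replicate", "ct", "template"]


def write_ct_table(table: pd.DataFrame, path: str) -> None:
    table[CT_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_ct_table(path: str) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t", na_values=[MISSING])
    missing = set(CT_COLUMNS) - set(tbl.columns)
    if missing:
        raise ParseError(f"{path}: line 1: missing columns {sorted(missing)}")
    # pandas reads an all-missing allele column as float NaN; keep as object
    tbl["allele"] = tbl["allele"].astype(object).where(tbl["allele"].notna(), None)
    return tbl
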