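"""Readers and writers for the pipeline's on-disk formats.

All tables are plain text: dosages as TSV (and a minimal VCF with GT
fields), NPX as a wide CSV plus a per-assay LOD/annotation sidecar CSV,
covariates and gene annotation as TSV, outcome summary statistics as TSV
with the conventional GWAS column layout.  Every writer has a matching
reader and round-trips exactly (asserted in tests).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import OUTCOME_COLUMNS, GenotypeMatrix, NPXMatrix

__all__ = [
    "write_dosage_tsv", "read_dosage_tsv", "write_vcf",
    "write_npx_csv", "read_npx_csv",
    "write_outcome_tsv", "read_outcome_tsv",
    "write_covariates_tsv", "read_covariates_tsv",
    "write_gene_annotation", "read_gene_annotation",
    "write_json", "read_json",
]

_VARIANT_META = ["id", "chrom", "pos", "effect_allele", "other_allele", "eaf"]


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    """Variant-major dosage table: metadata columns then one column per sample."""
    meta = geno.variants[_VARIANT_META].copy()
    dos = pd.DataFrame(geno.dosages.T, columns=geno.sample_ids)
    pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_ids = [c for c in df.columns if c not in _VARIANT_META]
    variants = df[_VARIANT_META].copy()
    variants["region"] = -1
    dosages = df[sample_ids].to_numpy(dtype=np.uint8).T
    return GenotypeMatrix(dosages=dosages, variants=variants, sample_ids=sample_ids)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT fields; dosage d maps to 0/0, 0/1 or 1/1
    (phase is not modelled).  REF is the other allele, ALT the effect
    allele, so the ALT dosage equals the effect-allele dosage."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pqtlmr-simulate\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = geno.variants["chrom"].astype(str).unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        for j, row in enumerate(geno.variants.itertuples(index=False)):
            gts = "\t".join(gt_map[int(d)] for d in geno.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.other_allele}\t"
                     f"{row.effect_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def write_npx_csv(npx: NPXMatrix, values_path: str | Path,
                  assay_path: str | Path) -> None:
    """Wide CSV (rows = samples) plus an assay sidecar holding gene
    coordinates, panel and per-assay LOD."""
    npx.frame().rename_axis("sample_id").to_csv(values_path, float_format="%.8g")
    npx.assays.to_csv(assay_path, index=False, float_format="%.8g")


def read_npx_csv(values_path: str | Path, assay_path: str | Path) -> NPXMatrix:
    values = pd.read_csv(values_path, index_col="sample_id")
    assays = pd.read_csv(assay_path, dtype={"chrom": str})
    values = values[assays["protein_id"].tolist()]
    mat = values.to_numpy(dtype=float)
    below = mat < assays["lod"].to_numpy(dtype=float)[None, :]
    return NPXMatrix(values=mat, sample_ids=list(values.index.astype(str)),
                     assays=assays, below_lod=below)


def write_outcome_tsv(outcome: pd.DataFrame, path: str | Path) -> None:
    outcome[OUTCOME_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_outcome_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_covariates_tsv(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_gene_annotation(assays: pd.DataFrame, path: str | Path) -> None:
    cols = ["protein_id", "gene", "chrom", "gene_start", "gene_end", "panel"]
    assays[[c for c in cols if c in assays.columns]].to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
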