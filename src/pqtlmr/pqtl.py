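"""Cis-pQTL mapping.

For each protein, variants within 1 Mbp of the encoding gene are tested
for additive association with NPX, adjusting for age, BMI and 10 genetic
principal components.  Multiple testing is handled the way large
cis-scan studies do it: count the number of *independent* variants
(pairwise r^2 < 0.1, position-order greedy pruning) per region, and
divide alpha = 0.05 by the mean independent count across regions to get
one global p-value threshold.  Significant, mutually independent hits
are then selected per region by greedy p-ordered clumping.

Counting independence in position order (not p order) keeps the test
burden independent of the association results; clumping of hits uses p
order because it selects signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import ols_scan
from .simulate import GenotypeMatrix, NPXMatrix

__all__ = [
    "CisRegion", "define_cis_region", "cis_scan", "count_independent",
    "significance_threshold", "select_pqtl", "pqtl_scan_all",
]

DEFAULT_WINDOW = 1_000_000
PC_COLUMNS = [f"PC{i}" for i in range(1, 11)]


@dataclass
class CisRegion:
    protein_id: str
    chrom: str
    window_start: int
    window_end: int
    variant_ids: list[str]
    columns: np.ndarray          # column indices into the genotype matrix

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


def define_cis_region(assay: pd.Series, variants: pd.DataFrame,
                      window: int = DEFAULT_WINDOW) -> CisRegion:
    """1-based inclusive window [gene_start - window, gene_end + window],
    clipped at 1, restricted to the gene's chromosome."""
    for fieldname in ("chrom", "gene_start", "gene_end"):
        if fieldname not in assay or pd.isna(assay[fieldname]):
            raise ValueError(f"assay {assay.get('protein_id', '?')} lacks {fieldname}")
    start = max(1, int(assay["gene_start"]) - window)
    end = int(assay["gene_end"]) + window
    mask = ((variants["chrom"].astype(str) == str(assay["chrom"]))
            & (variants["pos"] >= start) & (variants["pos"] <= end)).to_numpy()
    cols = np.flatnonzero(mask)
    sub = variants.iloc[cols]
    order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
    cols = cols[order]
    sub = sub.iloc[order]
    return CisRegion(
        protein_id=str(assay.get("protein_id", "?")), chrom=str(assay["chrom"]),
        window_start=start, window_end=end,
        variant_ids=sub["id"].tolist(), columns=np.asarray(cols, dtype=int),
    )


def cis_scan(npx_column: np.ndarray, genotypes: GenotypeMatrix,
             covariates: pd.DataFrame, region: CisRegion,
             maf_min: float = 0.01, standardise: bool = True) -> pd.DataFrame:
    """Per-variant additive OLS within one cis region.

    NPX is z-scaled by default so betas are in NPX SD per effect-allele
    copy.  Variants below the MAF floor are removed before testing;
    zero-variance dosages are reported with ``ok=False``.
    """
    if region.n_variants == 0:
        raise ValueError(f"region {region.protein_id} has no variants")
    y = np.asarray(npx_column, dtype=float)
    if standardise:
        sd = y.std()
        if sd <= 0:
            raise ValueError("NPX column has zero variance")
        y = (y - y.mean()) / sd
    cov = covariates[["age", "bmi", *PC_COLUMNS]].to_numpy(dtype=float)
    g = genotypes.dosages[:, region.columns].astype(float)
    eaf = g.mean(axis=0) / 2.0
    maf = np.minimum(eaf, 1.0 - eaf)
    keep = maf >= maf_min
    if not keep.any():
        raise ValueError(f"region {region.protein_id} empty after MAF filter")
    g = g[:, keep]
    meta = genotypes.variants.iloc[region.columns[keep]].reset_index(drop=True)
    res = ols_scan(y, g, cov)
    out = meta[["id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out["protein_id"] = region.protein_id
    out["eaf"] = eaf[keep]
    out["beta"] = res.beta
    out["se"] = res.se
    out["p"] = res.p
    out["n"] = res.n
    out["ok"] = res.ok
    return out


def _r2_matrix(dosages: np.ndarray) -> np.ndarray:
    g = np.asarray(dosages, dtype=float)
    sd = g.std(axis=0)
    sd[sd <= 0] = np.nan
    gc = (g - g.mean(axis=0)) / sd
    r = (gc.T @ gc) / g.shape[0]
    return np.nan_to_num(r * r)


def count_independent(region_dosages: np.ndarray, r2_max: float = 0.1) -> int:
    """Greedy position-order pruning: a variant is kept iff its r^2 with
    every previously kept variant is below ``r2_max``."""
    g = np.asarray(region_dosages, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    if g.shape[1] == 0:
        raise ValueError("at least one variant is required")
    r2 = _r2_matrix(g)
    kept: list[int] = []
    for j in range(g.shape[1]):
        if all(r2[j, k] < r2_max for k in kept):
            kept.append(j)
    return max(len(kept), 1)  # a region with >=1 variant has >=1 independent variant


def significance_threshold(mean_independent: float, alpha: float = 0.05) -> float:
    """Global cis threshold: alpha divided by the mean independent count."""
    if mean_independent < 1:
        raise ValueError("mean independent count must be >= 1")
    return alpha / mean_independent


def _clump(order: np.ndarray, r2: np.ndarray, r2_max: float) -> list[int]:
    kept: list[int] = []
    for j in order:
        if all(r2[j, k] < r2_max for k in kept):
            kept.append(int(j))
    return kept


def select_pqtl(results: pd.DataFrame, threshold: float,
                region_dosages: np.ndarray, r2_max: float = 0.1) -> pd.DataFrame:
    """Greedy p-ordered clumping of significant variants in one region.

    The most significant variant below the threshold is taken first;
    everything with r^2 >= ``r2_max`` against a kept variant is
    discarded; ranks record selection order.  Ties in p break by lower
    SE, then position.  ``region_dosages`` columns must align with
    ``results`` rows.
    """
    res = results.reset_index(drop=True)
    g = np.asarray(region_dosages, dtype=float)
    if g.shape[1] != len(res):
        raise ValueError("dosage columns do not align with result rows")
    usable = res["ok"].to_numpy() if "ok" in res else np.ones(len(res), bool)
    sig = np.flatnonzero((res["p"].to_numpy() < threshold) & usable)
    if sig.size == 0:
        return res.iloc[0:0].assign(rank=pd.Series(dtype=int))
    key = res.iloc[sig].sort_values(["p", "se", "pos"], kind="mergesort").index.to_numpy()
    r2 = _r2_matrix(g)
    kept = _clump(key, r2, r2_max)
    out = res.iloc[kept].copy()
    out["rank"] = np.arange(1, len(kept) + 1)
    return out.reset_index(drop=True)


def pqtl_scan_all(npx: NPXMatrix, genotypes: GenotypeMatrix,
                  covariates: pd.DataFrame, window: int = DEFAULT_WINDOW,
                  maf_min: float = 0.01, r2_independent: float = 0.1,
                  alpha: float = 0.05, alpha_fixed: float | None = None,
                  standardise: bool = True) -> dict:
    """Scan every assayed protein's cis region and select pQTL hits.

    Returns a dict with per-region summaries, the full association
    table, the global threshold and the hit table.  Assays without gene
    coordinates are skipped with a warning record rather than an error.
    """
    region_rows, assoc_frames, hit_frames, skipped = [], [], [], []
    regions: dict[str, CisRegion] = {}
    scans: dict[str, pd.DataFrame] = {}
    for j in range(npx.n_assays):
        assay = npx.assays.iloc[j]
        try:
            region = define_cis_region(assay, genotypes.variants, window=window)
        except ValueError as exc:
            skipped.append({"protein_id": assay.get("protein_id", "?"),
                            "reason": str(exc)})
            continue
        if region.n_variants == 0:
            skipped.append({"protein_id": region.protein_id,
                            "reason": "no variants in cis window"})
            continue
        g = genotypes.dosages[:, region.columns].astype(float)
        n_ind = count_independent(g, r2_max=r2_independent)
        scan = cis_scan(npx.values[:, j], genotypes, covariates, region,
                        maf_min=maf_min, standardise=standardise)
        regions[region.protein_id] = region
        scans[region.protein_id] = scan
        region_rows.append({"protein_id": region.protein_id,
                            "chrom": region.chrom,
                            "window_start": region.window_start,
                            "window_end": region.window_end,
                            "n_variants": region.n_variants,
                            "n_independent": n_ind})
        assoc_frames.append(scan)
    region_summary = pd.DataFrame(region_rows)
    if region_summary.empty:
        raise ValueError("no testable cis regions")
    mean_ind = float(region_summary["n_independent"].mean())
    threshold = alpha_fixed if alpha_fixed is not None else \
        significance_threshold(mean_ind, alpha=alpha)
    for pid, scan in scans.items():
        cols = regions[pid].columns
        # align dosages with the post-MAF-filter scan rows
        id_to_col = dict(zip(genotypes.variants["id"].iloc[cols], cols))
        use = [id_to_col[i] for i in scan["id"]]
        hits = select_pqtl(scan, threshold, genotypes.dosages[:, use].astype(float),
                           r2_max=r2_independent)
        if len(hits):
            hit_frames.append(hits)
    hits = pd.concat(hit_frames, ignore_index=True) if hit_frames else \
        assoc_frames[0].iloc[0:0].assign(rank=pd.Series(dtype=int))
    return {
        "regions": regions,
        "region_summary": region_summary,
        "associations": pd.concat(assoc_frames, ignore_index=True),
        "mean_independent": mean_ind,
        "threshold": float(threshold),
        "hits": hits,
        "skipped": skipped,
    }
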