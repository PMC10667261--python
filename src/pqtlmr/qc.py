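"""Affinity-proteomics quality control.

Three steps mirror the standard Olink-style workflow: per-assay
detectability (fraction of samples with NPX strictly above the assay's
limit of detection), inclusion filtering of assays by detectability, and
PCA-based sample outlier exclusion.  Sub-LOD values in retained assays
are kept, not masked — LOD censoring only flags, it never deletes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .simulate import NPXMatrix

__all__ = ["QCReport", "detectability", "filter_assays", "pca_outliers", "run_qc"]


@dataclass
class QCReport:
    detectability: pd.Series                       # per-assay fraction above LOD (NaN if all missing)
    excluded_samples: list[dict] = field(default_factory=list)
    excluded_assays: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.detectability.rename("detectability").rename_axis("protein_id").reset_index()


def detectability(npx: NPXMatrix) -> pd.Series:
    """Fraction of non-missing values strictly above the assay LOD.

    Assays where every value is missing get NaN (undefined, flagged by
    the caller); missing values are excluded from the denominator.
    """
    vals = npx.values
    lod = npx.assays["lod"].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    above = (vals > lod[None, :]) & finite
    denom = finite.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, above.sum(axis=0) / denom, np.nan)
    return pd.Series(frac, index=npx.assays["protein_id"].tolist())


def filter_assays(npx: NPXMatrix, min_detect: float = 0.25) -> tuple[NPXMatrix, list[dict]]:
    """Retain assays with detectability strictly greater than ``min_detect``.

    Strict inequality implements the published rule that assays with
    more than 75% of values below LOD are dropped while those with more
    than 25% detectability are kept; a detectability of exactly
    ``min_detect`` is therefore excluded.  Sub-LOD values in retained
    assays are untouched.
    """
    if not 0.0 <= min_detect <= 1.0:
        raise ValueError(f"min_detect must be in [0, 1], got {min_detect}")
    det = detectability(npx)
    keep = det.to_numpy() > min_detect
    # all-missing assays (NaN detectability) fail the comparison and drop out
    excluded = [
        {"protein_id": pid, "reason": "all values missing"} if not np.isfinite(d)
        else {"protein_id": pid, "reason": f"detectability {d:.3f} <= {min_detect}"}
        for pid, d, k in zip(det.index, det.to_numpy(), keep) if not k
    ]
    return npx.subset_assays(np.flatnonzero(keep)), excluded


def pca_outliers(npx: NPXMatrix, n_components: int = 2, z_cut: float = 5.0) -> list[dict]:
    """Samples scoring beyond ``z_cut`` SDs on any leading component.

    Missing values are mean-imputed for the decomposition only.  Returns
    one record per excluded sample with the offending component and its
    standardised score.
    """
    x = np.array(npx.values, dtype=float)
    if x.shape[1] < n_components:
        raise ValueError("fewer assays than requested components")
    col_mean = np.nanmean(x, axis=0)
    nan_mask = ~np.isfinite(x)
    x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    x = x - x.mean(axis=0)
    if not np.any(x.std(axis=0) > 1e-12):
        raise ValueError("degenerate (constant) NPX matrix; PCA undefined")
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(x)
    sd = scores.std(axis=0, ddof=1)
    sd[sd <= 0] = np.inf
    z = (scores - scores.mean(axis=0)) / sd
    out = []
    for i in np.flatnonzero(np.any(np.abs(z) > z_cut, axis=1)):
        comp = int(np.argmax(np.abs(z[i])))
        out.append({"sample_id": npx.sample_ids[i], "component": comp + 1,
                    "score": float(z[i, comp]), "reason": f"|PC{comp + 1} z| > {z_cut}"})
    return out


def run_qc(npx: NPXMatrix, min_detect: float = 0.25, n_components: int = 2,
           z_cut: float = 5.0) -> tuple[NPXMatrix, QCReport]:
    """Full QC pass: detectability -> assay filter -> PCA sample exclusion."""
    det = detectability(npx)
    filtered, excluded_assays = filter_assays(npx, min_detect)
    excluded_samples = pca_outliers(filtered, n_components=n_components, z_cut=z_cut)
    if excluded_samples:
        bad = {e["sample_id"] for e in excluded_samples}
        keep = np.array([i for i, s in enumerate(filtered.sample_ids) if s not in bad])
        filtered = filtered.subset_samples(keep)
    return filtered, QCReport(detectability=det, excluded_samples=excluded_samples,
                              excluded_assays=excluded_assays)
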