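"""Per-protein association with baseline clinical characteristics.

Each protein is regressed on seven baseline characteristics in one
multivariable OLS model:

    NPX ~ age + bmi + menopause(pre vs peri) + menopause(pre vs post)
          + birth_times + hrt_status + alcohol_gram_week + smoking_status

Menopause contributes two dummy contrasts but counts as one
characteristic, so the family has 7 characteristics and 8 coefficients
per protein.  Reference levels: pre-menopause, never/past HRT,
never/past smoking.  P-values are corrected with Benjamini–Hochberg over
the whole n_proteins x 7 family by default.

A separate incident case-control model regresses NPX on case status
adjusted for age, BMI and sample storage time, judged at a 5% FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import NPXMatrix

__all__ = [
    "CLINICAL_TERMS", "build_clinical_design", "fit_clinical_model",
    "fdr_adjust", "case_control_assoc", "clinical_scan", "case_control_scan",
]

# term -> characteristic family (menopause has two contrasts, one family)
CLINICAL_TERMS = {
    "age": "age",
    "bmi": "bmi",
    "menopause_preVSperi": "menopause",
    "menopause_preVSpost": "menopause",
    "birth_times": "birth_times",
    "hrt_current": "hrt",
    "alcohol_gram_week": "alcohol",
    "smoking_current": "smoking",
}
N_CHARACTERISTICS = 7


def build_clinical_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded design for the clinical model (no intercept column).

    Rows with any missing modelled covariate are dropped listwise; the
    returned frame keeps the original index so callers can align the
    response.
    """
    need = ["age", "bmi", "menopause", "birth_times", "hrt_status",
            "alcohol_gram_week", "smoking_status"]
    cov = covariates[need].copy()
    cov = cov.dropna(axis=0, how="any")
    design = pd.DataFrame(index=cov.index)
    design["age"] = cov["age"].astype(float)
    design["bmi"] = cov["bmi"].astype(float)
    design["menopause_preVSperi"] = (cov["menopause"] == "peri").astype(float)
    design["menopause_preVSpost"] = (cov["menopause"] == "post").astype(float)
    design["birth_times"] = cov["birth_times"].astype(float)
    design["hrt_current"] = (cov["hrt_status"] == "current").astype(float)
    design["alcohol_gram_week"] = cov["alcohol_gram_week"].astype(float)
    design["smoking_current"] = (cov["smoking_status"] == "current").astype(float)
    return design


def _check_rank(x: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the near-dependent columns via the QR diagonal
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = diag < 1e-8 * diag.max()
        names = ["intercept"] + list(x.columns)
        collinear = [n for n, b in zip(names, bad) if b]
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")


def _ols_terms(y: np.ndarray, design: pd.DataFrame, protein_id: str,
               term_map: dict[str, str]) -> pd.DataFrame:
    n_dropped_y = int(np.sum(~np.isfinite(y)))
    keep = np.isfinite(y)
    y, design = y[keep], design.loc[keep]
    if len(y) < design.shape[1] + 2:
        raise ValueError("too few complete cases for the clinical model")
    if np.std(y) < 1e-12:
        rows = [{"protein_id": protein_id, "term": t, "characteristic": c,
                 "beta": 0.0, "se": np.nan, "p": 1.0, "n": len(y),
                 "degenerate": True} for t, c in term_map.items()]
        return pd.DataFrame(rows)
    _check_rank(design)
    x = sm.add_constant(design.to_numpy(dtype=float))
    fit = sm.OLS(y, x).fit()
    rows = []
    for j, (term, char) in enumerate(term_map.items(), start=1):
        rows.append({"protein_id": protein_id, "term": term, "characteristic": char,
                     "beta": float(fit.params[j]), "se": float(fit.bse[j]),
                     "p": float(fit.pvalues[j]), "n": len(y), "degenerate": False})
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = n_dropped_y
    return out


def fit_clinical_model(npx_column: np.ndarray, covariates: pd.DataFrame,
                       protein_id: str = "protein") -> pd.DataFrame:
    """One protein against the seven baseline characteristics (8 terms)."""
    y_full = np.asarray(npx_column, dtype=float)
    if len(y_full) != len(covariates):
        raise ValueError("covariate rows do not align with the NPX column")
    design = build_clinical_design(covariates)
    y = y_full[covariates.index.get_indexer(design.index)]
    return _ols_terms(y, design, protein_id, CLINICAL_TERMS)


def fdr_adjust(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with denominator ``m``.

    ``m`` may exceed ``len(p_values)`` to correct a sub-vector against a
    larger test family (the full-family convention used when p-values
    are produced protein by protein but corrected study-wide).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"m ({m}) must be >= number of p-values ({k})")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(k)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def case_control_assoc(npx_column: np.ndarray, covariates: pd.DataFrame,
                       protein_id: str = "protein") -> pd.DataFrame:
    """Incident-case association: NPX ~ case + age + bmi + storage_time."""
    status = covariates["case_status"]
    if status.nunique() < 2:
        raise ValueError("both cases and controls are required")
    design = pd.DataFrame({
        "case": (status == "case").astype(float),
        "age": covariates["age"].astype(float),
        "bmi": covariates["bmi"].astype(float),
        "storage_time": covariates["storage_time"].astype(float),
    })
    keep = design.notna().all(axis=1).to_numpy()
    design = design.loc[keep]
    y = np.asarray(npx_column, dtype=float)[keep]
    return _ols_terms(y, design, protein_id,
                      {"case": "case_status", "age": "age", "bmi": "bmi",
                       "storage_time": "storage_time"}).query("term == 'case'") \
        .reset_index(drop=True)


def clinical_scan(npx: NPXMatrix, covariates: pd.DataFrame,
                  m: int | None = None) -> pd.DataFrame:
    """All proteins against the clinical model, with family-wide FDR.

    By default the correction denominator is ``n_assays * 7`` (one slot
    per characteristic), matching the convention of correcting for the
    number of protein-characteristic pairs; pass ``m`` to use the exact
    coefficient count instead.
    """
    frames = [fit_clinical_model(npx.values[:, j], covariates,
                                 protein_id=npx.assays["protein_id"].iloc[j])
              for j in range(npx.n_assays)]
    out = pd.concat(frames, ignore_index=True)
    if m is None:
        m = npx.n_assays * N_CHARACTERISTICS
    m = max(m, len(out))
    out["q"] = fdr_adjust(out["p"].to_numpy(), m=m)
    return out


def case_control_scan(npx: NPXMatrix, covariates: pd.DataFrame,
                      fdr: float = 0.05) -> pd.DataFrame:
    """Incident case-control association per protein at the given FDR."""
    frames = [case_control_assoc(npx.values[:, j], covariates,
                                 protein_id=npx.assays["protein_id"].iloc[j])
              for j in range(npx.n_assays)]
    out = pd.concat(frames, ignore_index=True)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out
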