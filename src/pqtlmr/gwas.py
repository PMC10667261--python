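"""Vectorised per-variant association engines.

Two workhorses used throughout the pipeline:

``ols_scan``
    Covariate-adjusted linear association of a quantitative trait with
    every column of a dosage matrix, computed by Frisch–Waugh
    residualisation: trait and dosages are projected off the covariate
    design once, then each variant's slope comes from a univariate
    regression of residual on residual.  Betas, SEs and two-sided t
    p-values are identical to fitting the full joint model per variant
    (asserted against statsmodels in the test suite) at a fraction of
    the cost.

``logistic_gwas``
    Per-variant logistic regression (intercept + dosage) of a binary
    phenotype, Newton–Raphson vectorised across variants.  This is the
    standard case-control GWAS model; it emits the log-odds-ratio beta,
    its Wald SE, and the two-sided normal p-value per variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["ols_scan", "logistic_gwas", "ScanResult"]


@dataclass
class ScanResult:
    """Per-variant association estimates (arrays aligned to input columns)."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: int
    ok: np.ndarray  # False where the variant was skipped (zero variance / no convergence)


def _residualise(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Project y (vector or matrix of columns) off span(design)."""
    q, _ = np.linalg.qr(design)
    return y - q @ (q.T @ y)


def ols_scan(y: np.ndarray, dosages: np.ndarray, covariates: np.ndarray | None = None) -> ScanResult:
    """Additive-model scan of trait ``y`` on each dosage column.

    Parameters
    ----------
    y : (n,) trait vector.
    dosages : (n, v) dosage matrix.
    covariates : (n, k) covariate matrix, without intercept (added here).

    Zero-variance dosage columns (after residualisation) are flagged
    ``ok=False`` with NaN estimates rather than raising.
    """
    y = np.asarray(y, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim == 1:
        dosages = dosages[:, None]
    n = y.shape[0]
    if dosages.shape[0] != n:
        raise ValueError(f"dosage rows ({dosages.shape[0]}) != trait length ({n})")
    if covariates is None:
        design = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        design = np.column_stack([np.ones(n), covariates])
    k_full = design.shape[1] + 1  # + the dosage term
    df = n - k_full
    if df <= 0:
        raise ValueError("not enough samples for the requested design")

    y_r = _residualise(y, design)
    g_r = _residualise(dosages, design)
    sxx = np.einsum("ij,ij->j", g_r, g_r)
    sxy = g_r.T @ y_r
    syy = float(y_r @ y_r)

    ok = sxx > 1e-12 * n
    beta = np.full(sxx.shape, np.nan)
    se = np.full(sxx.shape, np.nan)
    p = np.full(sxx.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[ok] = sxy[ok] / sxx[ok]
        rss = np.maximum(syy - beta[ok] ** 2 * sxx[ok], 0.0)
        se[ok] = np.sqrt(rss / df / sxx[ok])
        tval = beta[ok] / se[ok]
        p[ok] = 2.0 * stats.t.sf(np.abs(tval), df)
    # guard against exact-fit p=0 downstream (p must stay in (0, 1])
    p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
    return ScanResult(beta=beta, se=se, p=p, n=n, ok=ok)


def logistic_gwas(
    dosages: np.ndarray,
    y: np.ndarray,
    max_iter: int = 30,
    tol: float = 1e-8,
) -> ScanResult:
    """Univariate logistic regression of case status on each dosage column.

    Newton iterations are run simultaneously for all variants; each
    variant's 2x2 information matrix is solved in closed form.
    """
    g = np.asarray(dosages, dtype=np.float64)
    if g.ndim == 1:
        g = g[:, None]
    y = np.asarray(y, dtype=np.float64)
    n, v = g.shape
    if y.shape[0] != n:
        raise ValueError("phenotype length does not match dosage rows")
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("phenotype must contain both cases and controls")

    a = np.full(v, special.logit(ybar))
    b = np.zeros(v)
    active = g.std(axis=0) > 1e-12
    idx = np.flatnonzero(active)
    ga = g[:, idx]
    aa, ba = a[idx].copy(), b[idx].copy()
    converged = np.zeros(idx.size, dtype=bool)
    s0 = s1 = s2 = None
    for _ in range(max_iter):
        eta = aa + ga * ba
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        s0 = w.sum(axis=0)
        s1 = np.einsum("ij,ij->j", w, ga)
        s2 = np.einsum("ij,ij,ij->j", w, ga, ga)
        u0 = r.sum(axis=0)
        u1 = np.einsum("ij,ij->j", r, ga)
        det = s0 * s2 - s1 * s1
        det = np.where(det > 1e-300, det, np.nan)
        da = (s2 * u0 - s1 * u1) / det
        db = (s0 * u1 - s1 * u0) / det
        da = np.nan_to_num(da)
        db = np.nan_to_num(db)
        aa += da
        ba += db
        converged = (np.abs(da) < tol) & (np.abs(db) < tol)
        if converged.all():
            break
    det = s0 * s2 - s1 * s1
    with np.errstate(invalid="ignore", divide="ignore"):
        se_a = np.sqrt(s0 / det)
    ok_a = converged & np.isfinite(se_a) & (se_a > 0)

    beta = np.full(v, np.nan)
    se = np.full(v, np.nan)
    p = np.full(v, np.nan)
    ok = np.zeros(v, dtype=bool)
    beta[idx] = np.where(ok_a, ba, np.nan)
    se[idx] = np.where(ok_a, se_a, np.nan)
    z = beta[idx] / se[idx]
    p[idx] = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    ok[idx] = ok_a
    return ScanResult(beta=beta, se=se, p=p, n=n, ok=ok)
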