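"""Presentation layer: volcano and regional mirror plots.

Plotting never makes analytic decisions — verdicts and significance
flags are computed upstream and only rendered here.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .coloc import MirrorRegionData  # noqa: E402

__all__ = ["volcano_plot", "mirror_plot"]


def volcano_plot(table: pd.DataFrame, path: str | Path, beta_col: str = "beta",
                 p_col: str = "p", label_col: str = "protein_id",
                 alpha: float | None = None, title: str = "") -> None:
    """Effect size vs -log10 p, one point per test."""
    fig, ax = plt.subplots(figsize=(6, 5))
    x = table[beta_col].to_numpy(dtype=float)
    y = -np.log10(np.clip(table[p_col].to_numpy(dtype=float), 1e-300, 1.0))
    ax.scatter(x, y, s=12, alpha=0.7, edgecolors="none", color="#41618c")
    if alpha is not None:
        ax.axhline(-np.log10(alpha), ls="--", lw=0.8, color="grey")
        top = table[table[p_col] < alpha]
        for _, row in top.nsmallest(10, p_col).iterrows():
            ax.annotate(str(row[label_col]), (row[beta_col],
                        -np.log10(max(row[p_col], 1e-300))), fontsize=7)
    ax.set_xlabel("beta")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def mirror_plot(data: MirrorRegionData, path: str | Path, title: str = "") -> None:
    """Exposure associations above, outcome associations below a shared
    genomic axis (Mbp); points coloured by r^2 to the lead pQTL."""
    t = data.table
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 6),
                                   gridspec_kw={"hspace": 0.05})
    x = t["pos"].to_numpy(dtype=float) / 1e6
    c = t["r2_to_lead"].to_numpy(dtype=float)
    have_ld = np.isfinite(c).all()
    kw = dict(s=18, cmap="viridis", vmin=0, vmax=1) if have_ld else dict(s=18)
    sc = ax1.scatter(x, t["mlog10p_exposure"], c=c if have_ld else "#41618c", **kw)
    ax2.scatter(x, -t["mlog10p_outcome"], c=c if have_ld else "#8c4141", **kw)
    for ax, lead in ((ax1, data.lead_exposure_id), (ax2, data.lead_outcome_id)):
        row = t[t["id"] == lead]
        if len(row):
            ax.axvline(float(row["pos"].iloc[0]) / 1e6, ls=":", lw=0.8, color="grey")
    ax1.set_ylabel(r"exposure $-\log_{10} p$")
    ax2.set_ylabel(r"outcome $-\log_{10} p$")
    ax2.set_xlabel("position (Mbp)")
    ax1.set_title(title or data.protein_id)
    if have_ld:
        fig.colorbar(sc, ax=(ax1, ax2), label=r"$r^2$ to lead pQTL", shrink=0.8)
        fig.savefig(path, dpi=150)
    else:
        fig.tight_layout()
        fig.savefig(path, dpi=150)
    plt.close(fig)
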