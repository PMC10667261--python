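"""Synthetic cohort generator.

Emulates the statistical structure of a proteogenomic MR study without
any external data:

* **Genotypes** — per cis region, haplotypes arise from a latent
  Gaussian AR(1) process thresholded at each variant's minor-allele-
  frequency quantile; two haplotypes sum to a dosage in {0, 1, 2}.  The
  AR(1) decay gives tunable, monotone LD for pruning and clumping tests.
* **NPX protein levels** — one (optionally two) cis variant(s) explain
  ``cis_h2`` of the variance, standardised covariates add fixed effects,
  Gaussian noise fills the remainder so the total variance is 1 NPX SD;
  a per-assay limit of detection is placed at the ``lod_quantile`` of the
  simulated distribution and sub-LOD values are flagged but retained.
* **Outcome summary statistics** — a fresh cohort's case status is drawn
  from a logistic model on the genetically regulated protein liability
  (plus, under ``ld_confounded``, a direct variant effect in LD with the
  lead pQTL), then per-variant logistic GWAS summary rows are emitted.
  Discovery and replication cohorts use independent sub-streams.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .config import ConfigError, SimulationConfig
from .gwas import logistic_gwas
from .rng import substream

__all__ = [
    "GenotypeMatrix",
    "NPXMatrix",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_npx",
    "simulate_outcome_summary",
    "simulate_study",
]

OUTCOME_COLUMNS = [
    "chrom", "pos", "id", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n_case", "n_control",
]

_GENE_LENGTH = 10_000
_REGION_SPACING = 6_000_000
_CIS_WINDOW = 1_000_000

# allele pairs; the last two are strand-palindromic and appear at ~15%
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]
_ALLELE_WEIGHTS = np.array([0.30, 0.30, 0.125, 0.125, 0.075, 0.075])


@dataclass
class GenotypeMatrix:
    """Sample x variant dosages plus per-variant metadata.

    ``variants`` columns: id, chrom, pos, effect_allele, other_allele,
    eaf (empirical), maf (generating), region (protein index), is_lead,
    is_signal2.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def region_columns(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.variants["region"].to_numpy() == region)

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids,
                            columns=self.variants["id"].tolist())


@dataclass
class NPXMatrix:
    """Sample x protein NPX values with per-assay annotation and LOD.

    ``assays`` columns: protein_id, gene, chrom, gene_start, gene_end,
    panel, lod.  ``below_lod`` flags censored values, which are retained.
    ``truth`` carries the generating parameters for downstream
    simulation and truth-tracked tests; it is not consumed by any
    analysis stage.
    """

    values: np.ndarray
    sample_ids: list[str]
    assays: pd.DataFrame
    below_lod: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    def column(self, protein_id: str) -> np.ndarray:
        j = self.assays.index[self.assays["protein_id"] == protein_id]
        if len(j) != 1:
            raise KeyError(f"unknown protein_id {protein_id!r}")
        return self.values[:, j[0]]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.assays["protein_id"].tolist())

    def subset_assays(self, keep: np.ndarray) -> "NPXMatrix":
        keep = np.asarray(keep)
        return NPXMatrix(
            values=self.values[:, keep],
            sample_ids=list(self.sample_ids),
            assays=self.assays.iloc[keep].reset_index(drop=True),
            below_lod=None if self.below_lod is None else self.below_lod[:, keep],
            truth=self.truth,
        )

    def subset_samples(self, keep: np.ndarray) -> "NPXMatrix":
        keep = np.asarray(keep)
        return NPXMatrix(
            values=self.values[keep],
            sample_ids=[self.sample_ids[i] for i in keep],
            assays=self.assays,
            below_lod=None if self.below_lod is None else self.below_lod[keep],
            truth=self.truth,
        )


# ---------------------------------------------------------------------------
# region layout


def region_layout(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotation per protein: 22 chromosome labels are recycled and
    regions on a chromosome are spaced so cis windows never overlap."""
    rows = []
    for p in range(config.n_proteins):
        chrom = str(p % 22 + 1)
        slot = p // 22
        origin = 1 + slot * _REGION_SPACING
        gene_start = origin + _CIS_WINDOW + 1_500_000
        rows.append({
            "protein_id": f"P{p + 1:04d}",
            "gene": f"GENE{p + 1:04d}",
            "chrom": chrom,
            "gene_start": gene_start,
            "gene_end": gene_start + _GENE_LENGTH,
            "panel": "ExploreI" if p % 2 == 0 else "ExploreII",
        })
    return pd.DataFrame(rows)


def _variant_table(config: SimulationConfig) -> pd.DataFrame:
    rng = substream(config.seed, "variants")
    genes = region_layout(config)
    v = config.variants_per_region
    lead = v // 2
    signal2 = 0 if v > 1 else 0  # farthest-from-lead variant carries the second signal
    rows = []
    for p, gene in genes.iterrows():
        window_start = max(1, gene.gene_start - _CIS_WINDOW)
        window_end = gene.gene_end + _CIS_WINDOW
        pos = np.linspace(window_start, window_end, num=v, dtype=np.int64)
        mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=v)
        pair_idx = rng.choice(len(_ALLELE_PAIRS), size=v, p=_ALLELE_WEIGHTS)
        swap = rng.random(v) < 0.5
        for i in range(v):
            a, b = _ALLELE_PAIRS[pair_idx[i]]
            ea, oa = (b, a) if swap[i] else (a, b)
            rows.append({
                "id": f"rs{p + 1:04d}_{i + 1:03d}",
                "chrom": gene.chrom,
                "pos": int(pos[i]),
                "effect_allele": ea,
                "other_allele": oa,
                "maf": mafs[i],
                "region": p,
                "is_lead": i == lead,
                "is_signal2": config.n_cis_signals == 2 and i == signal2 and i != lead,
            })
    return pd.DataFrame(rows)


def _region_dosages(rng: np.random.Generator, n: int, mafs: np.ndarray,
                    rho: float) -> np.ndarray:
    """Two thresholded latent-AR(1) haplotypes summed to a dosage matrix."""
    v = mafs.shape[0]
    thr = stats.norm.ppf(mafs).astype(np.float32)
    innov_sd = np.float32(np.sqrt(1.0 - rho * rho))
    rho32 = np.float32(rho)
    dosage = np.zeros((n, v), dtype=np.uint8)
    for _hap in range(2):
        z = rng.standard_normal((n, v), dtype=np.float32)
        if rho > 0:
            for j in range(1, v):
                z[:, j] = rho32 * z[:, j - 1] + innov_sd * z[:, j]
        dosage += (z < thr[None, :]).astype(np.uint8)
    return dosage


def simulate_genotypes(config: SimulationConfig,
                       variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Exposure-cohort dosages for every cis region.

    Pass ``variants`` (a table from a previous call) to draw a fresh
    cohort from the same variant panel — the two-cohort design used for
    cross-study effect-size comparisons.
    """
    if variants is None:
        variants = _variant_table(config)
    else:
        variants = variants.drop(columns=["eaf"], errors="ignore").copy()
    n = config.n_samples
    blocks = []
    for p in range(config.n_proteins):
        mask = variants["region"].to_numpy() == p
        rng = substream(config.seed, "geno", "exposure", p)
        blocks.append(_region_dosages(rng, n, variants.loc[mask, "maf"].to_numpy(),
                                      config.ld_rho))
    dosages = np.concatenate(blocks, axis=1)
    variants = variants.copy()
    variants["eaf"] = dosages.mean(axis=0) / 2.0
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=variants, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Baseline characteristics of the exposure cohort.

    Distributions approximate a middle-aged female screening cohort;
    menopausal status depends on age; cases and controls are balanced by
    construction (the matched design is emulated, not re-implemented).
    """
    rng = substream(config.seed, "covariates")
    n = config.n_samples
    age = rng.normal(54.0, 9.0, n).clip(30, 80)
    bmi = rng.normal(25.5, 4.0, n).clip(16, 45)
    p_post = special.expit((age - 51.0) / 2.5)
    u = rng.random(n)
    menopause = np.where(u < p_post, "post", np.where(u < p_post + 0.12, "peri", "pre"))
    birth_times = rng.poisson(1.8, n)
    hrt = np.where(rng.random(n) < 0.07, "current", "never_or_past")
    alcohol = rng.gamma(shape=1.5, scale=30.0, size=n)
    smoking = np.where(rng.random(n) < 0.13, "current", "never_or_past")
    storage = rng.uniform(400, 3600, n)
    case = np.array(["control"] * n)
    case[rng.permutation(n)[: n // 2]] = "case"
    cov = pd.DataFrame({
        "sample_id": [f"S{i + 1:05d}" for i in range(n)],
        "age": age, "bmi": bmi, "menopause": menopause,
        "birth_times": birth_times, "hrt_status": hrt,
        "alcohol_gram_week": alcohol, "smoking_status": smoking,
        "storage_time": storage, "case_status": case,
    })
    pcs = rng.standard_normal((n, 10))
    for k in range(10):
        cov[f"PC{k + 1}"] = pcs[:, k]
    return cov


# ---------------------------------------------------------------------------
# NPX


def _signal_columns(variants: pd.DataFrame, region: int) -> tuple[np.ndarray, np.ndarray]:
    mask = variants["region"].to_numpy() == region
    lead = np.flatnonzero(mask & variants["is_lead"].to_numpy())
    sig2 = np.flatnonzero(mask & variants["is_signal2"].to_numpy())
    return lead, sig2


def simulate_npx(genotypes: GenotypeMatrix, covariates: pd.DataFrame,
                 config: SimulationConfig) -> NPXMatrix:
    """Cis-regulated NPX with covariate effects, unit variance and LOD flags."""
    if list(covariates["sample_id"]) != list(genotypes.sample_ids):
        raise ValueError("sample ids of genotypes and covariates do not align")
    rng = substream(config.seed, "npx")
    n, p_total = genotypes.n_samples, config.n_proteins
    variants = genotypes.variants

    cov_part = np.zeros(n)
    for name, eff in config.covariate_effects.items():
        x = covariates[name].to_numpy(dtype=float)
        sd = x.std()
        if sd <= 0:
            raise ValueError(f"covariate {name!r} is constant; cannot standardise")
        cov_part = cov_part + eff * (x - x.mean()) / sd
    var_cov = float(sum(e * e for e in config.covariate_effects.values()))
    noise_var = 1.0 - config.cis_h2 - var_cov
    noise_sd = float(np.sqrt(noise_var))

    case_mask = (covariates["case_status"].to_numpy() == "case").astype(float)

    values = np.empty((n, p_total))
    genes = region_layout(config)
    lods = np.empty(p_total)
    truth_rows = []
    for p in range(p_total):
        lead_col, sig2_col = _signal_columns(variants, p)
        cols = np.concatenate([lead_col, sig2_col])
        h2_per = config.cis_h2 / max(len(cols), 1)
        genetic = np.zeros(n)
        betas = []
        for c in cols:
            f = float(variants["maf"].iloc[c])
            var_g = 2.0 * f * (1.0 - f)
            b = float(np.sqrt(h2_per / var_g)) if h2_per > 0 else 0.0
            g = genotypes.dosages[:, c].astype(float)
            genetic = genetic + b * (g - 2.0 * f)
            betas.append(b)
        offset = rng.uniform(1.0, 8.0)
        y = offset + genetic + cov_part + noise_sd * rng.standard_normal(n)
        shift = dict(config.case_effects).get(p, 0.0)
        if shift:
            y = y + shift * case_mask
        values[:, p] = y
        lods[p] = np.quantile(y, config.lod_quantile) if config.lod_quantile > 0 else -np.inf
        causal = config.scenario == "causal" and p < config.n_causal
        truth_rows.append({
            "protein_index": p,
            "protein_id": genes["protein_id"].iloc[p],
            "signal_cols": cols.tolist(),
            "signal_ids": variants["id"].iloc[cols].tolist(),
            "beta_g": betas,
            "mafs": [float(variants["maf"].iloc[c]) for c in cols],
            "causal": bool(causal),
            "theta": config.theta if causal else 0.0,
        })

    assays = genes.copy()
    assays["lod"] = lods
    below = values < lods[None, :]
    truth = {
        "proteins": truth_rows,
        "cis_h2": config.cis_h2,
        "noise_var_outcome": 1.0 - config.cis_h2,
        "scenario": config.scenario,
    }
    return NPXMatrix(values=values, sample_ids=list(genotypes.sample_ids),
                     assays=assays, below_lod=below, truth=truth)


# ---------------------------------------------------------------------------
# outcome summary statistics


def _pick_confounder(genotypes: GenotypeMatrix, region: int,
                     target_r2: float) -> int:
    """Variant in the region whose dosage r^2 with the lead is closest to
    target (the lead itself excluded). Deterministic given the exposure
    genotypes."""
    cols = genotypes.region_columns(region)
    sub = genotypes.variants.iloc[cols]
    lead_col = int(cols[sub["is_lead"].to_numpy()][0])
    g = genotypes.dosages[:, cols].astype(float)
    lead = genotypes.dosages[:, lead_col].astype(float)
    with np.errstate(invalid="ignore"):
        r = np.array([np.corrcoef(lead, g[:, j])[0, 1] for j in range(g.shape[1])])
    r2 = np.nan_to_num(r * r)
    order = np.argsort(np.abs(r2 - target_r2))
    for j in order:
        if int(cols[j]) != lead_col:
            return int(cols[j])
    return lead_col  # single-variant region; degenerate but defined


def simulate_outcome_summary(genotypes: GenotypeMatrix, npx: NPXMatrix,
                             config: SimulationConfig, which: str) -> pd.DataFrame:
    """Case-control GWAS summary statistics for one outcome cohort.

    A fresh cohort of ``n_cases + n_controls`` individuals is simulated
    from the same variant panel; case status follows a logistic model on
    the genetically regulated protein liability (scenario ``causal``) or
    on a direct variant effect (``ld_confounded``); each variant is then
    summarised by univariate logistic regression.  ``which`` must be
    ``discovery`` or ``replication`` and selects an independent stream.
    """
    if which not in ("discovery", "replication"):
        raise ValueError("which must be 'discovery' or 'replication'")
    if config.scenario == "null" and config.theta != 0.0:
        raise ConfigError("theta: scenario=null forces theta=0")
    if not npx.truth:
        raise ValueError("npx does not carry generating truth; use simulate_npx")

    n_out = config.n_cases + config.n_controls
    k_target = config.n_cases / n_out
    variants = genotypes.variants
    regions = sorted(variants["region"].unique())
    noise_sd = float(np.sqrt(npx.truth["noise_var_outcome"]))

    def region_geno(p: int) -> np.ndarray:
        mask = variants["region"].to_numpy() == p
        rng = substream(config.seed, "geno", "outcome", which, p)
        return _region_dosages(rng, n_out, variants.loc[mask, "maf"].to_numpy(),
                               config.ld_rho)

    # pass 1: linear predictor from regions that touch the outcome
    eta0 = np.zeros(n_out)
    confounders: dict[int, int] = {}
    active = False
    for row in npx.truth["proteins"]:
        p = row["protein_index"]
        if config.scenario == "causal" and row["causal"] and row["theta"] != 0.0:
            g = region_geno(p).astype(np.float32)
            cols = genotypes.region_columns(p)
            local = {int(c): j for j, c in enumerate(cols)}
            liab_rng = substream(config.seed, "liability", which, p)
            liability = noise_sd * liab_rng.standard_normal(n_out)
            for b, c, f in zip(row["beta_g"], row["signal_cols"], row["mafs"]):
                liability = liability + b * (g[:, local[int(c)]] - 2.0 * f)
            eta0 = eta0 + row["theta"] * liability
            active = True
        elif config.scenario == "ld_confounded" and p < config.n_causal:
            conf_col = _pick_confounder(genotypes, p, config.confound_target_r2)
            confounders[p] = conf_col
            g = region_geno(p)
            cols = genotypes.region_columns(p)
            j = int(np.flatnonzero(cols == conf_col)[0])
            f = float(variants["maf"].iloc[conf_col])
            eta0 = eta0 + config.confound_log_or * (g[:, j].astype(float) - 2.0 * f)
            active = True

    if active:
        lo, hi = special.logit(k_target) - 30.0, special.logit(k_target) + 30.0
        alpha = optimize.brentq(
            lambda a: special.expit(a + eta0).mean() - k_target, lo, hi, xtol=1e-10)
    else:
        alpha = float(special.logit(k_target))

    case_rng = substream(config.seed, "case", which)
    y = (case_rng.random(n_out) < special.expit(alpha + eta0)).astype(np.float64)
    n_case, n_control = int(y.sum()), int(n_out - y.sum())

    # pass 2: per-variant logistic summary, region by region
    frames = []
    for p in regions:
        g = region_geno(p)
        res = logistic_gwas(g, y)
        mask = variants["region"].to_numpy() == p
        sub = variants.loc[mask, ["chrom", "pos", "id", "effect_allele",
                                  "other_allele"]].reset_index(drop=True)
        sub["eaf"] = g.mean(axis=0) / 2.0
        sub["beta"] = res.beta
        sub["se"] = res.se
        sub["p"] = res.p
        sub["n_case"] = n_case
        sub["n_control"] = n_control
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)

    # recode a deterministic fraction of variants to the opposite allele
    # orientation so downstream harmonisation has real work to do
    if config.allele_recode_fraction > 0:
        rec_rng = substream(config.seed, "recode", which)
        flip = rec_rng.random(len(out)) < config.allele_recode_fraction
        out.loc[flip, ["effect_allele", "other_allele"]] = (
            out.loc[flip, ["other_allele", "effect_allele"]].to_numpy())
        out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
        out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out = out[OUTCOME_COLUMNS].copy()
    out.attrs["which"] = which
    out.attrs["confounders"] = {
        int(k): str(variants["id"].iloc[v]) for k, v in confounders.items()}
    out.attrs["alpha"] = float(alpha)
    return out


def simulate_study(config: SimulationConfig) -> dict:
    """Convenience wrapper producing the full synthetic study.

    Returns a dict with genotypes, covariates, npx, outcome_discovery,
    outcome_replication and the generating truth.
    """
    geno = simulate_genotypes(config)
    cov = simulate_covariates(config)
    npx = simulate_npx(geno, cov, config)
    disc = simulate_outcome_summary(geno, npx, config, "discovery")
    rep = simulate_outcome_summary(geno, npx, config, "replication")
    return {
        "config": config,
        "genotypes": geno,
        "covariates": cov,
        "npx": npx,
        "outcome_discovery": disc,
        "outcome_replication": rep,
        "truth": npx.truth,
    }
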