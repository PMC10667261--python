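"""End-to-end orchestration: simulate -> QC -> clinical association ->
cis-pQTL scan -> MR discovery -> replication -> regional concordance.

Stages run in study order, each writing its tables before the next
starts.  The run manifest records the configuration, per-stage record
counts, the funnel (assays in -> post-QC -> with cis-pQTL -> MR-tested
-> significant -> replicated) and a checksum for every output file, so
identical (config, seed) pairs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .clinical import case_control_scan, clinical_scan
from .coloc import ld_lookup_from_dosages, lead_concordance, region_alignment
from .config import PipelineConfig
from .mr import clump_instruments, mr_screen, replicate
from .pqtl import pqtl_scan_all
from .qc import run_qc
from .simulate import simulate_study

__all__ = ["RunManifest", "run_pipeline", "analyse_study"]


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    seed: int
    version: str
    started: float
    finished: float = 0.0
    stage_counts: dict = field(default_factory=dict)
    funnel: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # path -> sha256
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config, "config_hash": self.config_hash,
            "seed": self.seed, "version": self.version,
            "started": self.started, "finished": self.finished,
            "stage_counts": self.stage_counts, "funnel": self.funnel,
            "outputs": self.outputs, "warnings": self.warnings,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps({"simulation": cfg.simulation.to_dict(),
                       "thresholds": vars(cfg.thresholds)}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def analyse_study(study: dict, thresholds=None) -> dict:
    """In-memory QC -> cis scan -> MR -> replication on a simulated study.

    The analytic core of :func:`run_pipeline` without file output or
    plotting, for operating-characteristic runs that repeat the whole
    analysis many times.  Returns the funnel counts plus the discovery
    and replication tables and the instrument map.
    """
    from .config import Thresholds

    thr = thresholds or Thresholds()
    geno, cov, npx = study["genotypes"], study["covariates"], study["npx"]
    npx_qc, _ = run_qc(npx, min_detect=thr.min_detect)
    if npx_qc.n_samples != npx.n_samples:
        keep_ids = set(npx_qc.sample_ids)
        keep = np.array([i for i, s in enumerate(geno.sample_ids) if s in keep_ids])
        from .simulate import GenotypeMatrix
        geno = GenotypeMatrix(dosages=geno.dosages[keep], variants=geno.variants,
                              sample_ids=[geno.sample_ids[i] for i in keep])
        cov = cov.iloc[keep].reset_index(drop=True)
    scan = pqtl_scan_all(npx_qc, geno, cov, maf_min=thr.maf_min,
                         r2_independent=thr.r2_independent, alpha=thr.alpha,
                         alpha_fixed=thr.alpha_pqtl)
    frame = geno.dosage_frame()
    instruments = {}
    for pid, hits in scan["hits"].groupby("protein_id", sort=True):
        g = frame[hits["id"].tolist()].to_numpy(dtype=float)
        instruments[pid] = clump_instruments(hits, g, r2_max=thr.r2_clump)
    mr_disc, untested = mr_screen(instruments, study["outcome_discovery"],
                                  alpha_discovery=thr.alpha_mr,
                                  outcome_id="discovery",
                                  palindrome_eaf_band=thr.palindrome_eaf_band)
    mr_rep = replicate(mr_disc, instruments, study["outcome_replication"],
                       alpha_rep=thr.alpha_rep,
                       palindrome_eaf_band=thr.palindrome_eaf_band)
    replicated = mr_rep.loc[mr_rep["replicated"], "protein_id"].tolist() \
        if len(mr_rep) else []
    return {
        "scan": scan,
        "instruments": instruments,
        "mr_discovery": mr_disc,
        "mr_replication": mr_rep,
        "untested": untested,
        "replicated_proteins": replicated,
        "funnel": {
            "assays_measured": npx.n_assays,
            "assays_post_qc": npx_qc.n_assays,
            "proteins_with_cis_pqtl": scan["hits"]["protein_id"].nunique()
            if len(scan["hits"]) else 0,
            "proteins_mr_tested": len(mr_disc),
            "proteins_mr_significant": int(mr_disc["significant"].sum())
            if len(mr_disc) else 0,
            "proteins_replicated": len(replicated),
        },
    }


def run_pipeline(config: PipelineConfig) -> RunManifest:
    from . import __version__

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    sim = config.simulation
    manifest = RunManifest(
        config={"simulation": sim.to_dict(), "thresholds": vars(thr)},
        config_hash=_config_hash(config), seed=sim.seed, version=__version__,
        started=time.time(),
    )

    def register(path: Path) -> None:
        manifest.outputs[str(path.relative_to(out_dir))] = _sha256(path)

    def stage(name: str, **counts) -> None:
        manifest.stage_counts[name] = counts

    # ---- simulate ---------------------------------------------------------
    study = simulate_study(sim)
    geno, cov, npx = study["genotypes"], study["covariates"], study["npx"]
    io.write_dosage_tsv(geno, out_dir / "dosages.tsv")
    io.write_npx_csv(npx, out_dir / "npx.csv", out_dir / "assays.csv")
    io.write_covariates_tsv(cov, out_dir / "covariates.tsv")
    io.write_gene_annotation(npx.assays, out_dir / "genes.tsv")
    io.write_outcome_tsv(study["outcome_discovery"], out_dir / "outcome_discovery.tsv")
    io.write_outcome_tsv(study["outcome_replication"], out_dir / "outcome_replication.tsv")
    truth = {"scenario": sim.scenario, "theta": sim.theta,
             "causal_proteins": [r["protein_id"] for r in npx.truth["proteins"]
                                 if r["causal"]],
             "confounders": study["outcome_discovery"].attrs.get("confounders", {}),
             "lead_variants": {r["protein_id"]: r["signal_ids"]
                               for r in npx.truth["proteins"]}}
    io.write_json(truth, out_dir / "truth.json")
    for f in ("dosages.tsv", "npx.csv", "assays.csv", "covariates.tsv", "genes.tsv",
              "outcome_discovery.tsv", "outcome_replication.tsv", "truth.json"):
        register(out_dir / f)
    stage("simulate", samples=geno.n_samples, variants=geno.n_variants,
          assays=npx.n_assays)

    # ---- proteomics QC ----------------------------------------------------
    npx_qc, qc_report = run_qc(npx, min_detect=thr.min_detect)
    qc_report.to_frame().to_csv(out_dir / "detectability.tsv", sep="\t", index=False)
    io.write_json({"excluded_samples": qc_report.excluded_samples,
                   "excluded_assays": qc_report.excluded_assays},
                  out_dir / "qc_report.json")
    register(out_dir / "detectability.tsv")
    register(out_dir / "qc_report.json")
    manifest.warnings += [{"stage": "qc", **e} for e in qc_report.excluded_samples]
    stage("qc", assays_in=npx.n_assays, assays_kept=npx_qc.n_assays,
          samples_kept=npx_qc.n_samples)

    # align genotypes/covariates with any QC sample exclusions
    if npx_qc.n_samples != npx.n_samples:
        keep_ids = set(npx_qc.sample_ids)
        keep = np.array([i for i, s in enumerate(geno.sample_ids) if s in keep_ids])
        geno.dosages = geno.dosages[keep]
        geno.sample_ids = [geno.sample_ids[i] for i in keep]
        cov = cov.iloc[keep].reset_index(drop=True)

    # ---- clinical associations -------------------------------------------
    clin = clinical_scan(npx_qc, cov)
    clin.to_csv(out_dir / "clinical_associations.tsv", sep="\t", index=False)
    register(out_dir / "clinical_associations.tsv")
    cc = case_control_scan(npx_qc, cov)
    cc.to_csv(out_dir / "case_control_associations.tsv", sep="\t", index=False)
    register(out_dir / "case_control_associations.tsv")
    stage("clinical", tests=len(clin),
          fdr_significant=int((clin["q"] < 0.05).sum()),
          case_control_significant=int(cc["significant"].sum()))

    # ---- cis-pQTL scan ----------------------------------------------------
    scan = pqtl_scan_all(npx_qc, geno, cov, maf_min=thr.maf_min,
                         r2_independent=thr.r2_independent, alpha=thr.alpha,
                         alpha_fixed=thr.alpha_pqtl)
    scan["region_summary"].to_csv(out_dir / "cis_regions.tsv", sep="\t", index=False)
    scan["associations"].to_csv(out_dir / "cis_associations.tsv", sep="\t",
                                index=False)
    scan["hits"].to_csv(out_dir / "pqtl_hits.tsv", sep="\t", index=False)
    for f in ("cis_regions.tsv", "cis_associations.tsv", "pqtl_hits.tsv"):
        register(out_dir / f)
    manifest.warnings += [{"stage": "pqtl_scan", **s} for s in scan["skipped"]]
    proteins_with_pqtl = scan["hits"]["protein_id"].nunique() if len(scan["hits"]) else 0
    stage("pqtl_scan", regions=len(scan["region_summary"]),
          mean_independent=scan["mean_independent"], threshold=scan["threshold"],
          hits=len(scan["hits"]), proteins_with_pqtl=proteins_with_pqtl)

    # ---- instruments ------------------------------------------------------
    dosage_frame = geno.dosage_frame()
    instruments = {}
    for pid, hits in scan["hits"].groupby("protein_id", sort=True):
        g = dosage_frame[hits["id"].tolist()].to_numpy(dtype=float)
        instruments[pid] = clump_instruments(hits, g, r2_max=thr.r2_clump)

    # ---- MR discovery + replication --------------------------------------
    mr_disc, untested = mr_screen(instruments, study["outcome_discovery"],
                                  alpha_discovery=thr.alpha_mr,
                                  outcome_id="discovery",
                                  palindrome_eaf_band=thr.palindrome_eaf_band)
    mr_disc.to_csv(out_dir / "mr_discovery.tsv", sep="\t", index=False)
    register(out_dir / "mr_discovery.tsv")
    manifest.warnings += [{"stage": "mr", **u} for u in untested]
    mr_rep = replicate(mr_disc, instruments, study["outcome_replication"],
                       alpha_rep=thr.alpha_rep,
                       palindrome_eaf_band=thr.palindrome_eaf_band)
    mr_rep.to_csv(out_dir / "mr_replication.tsv", sep="\t", index=False)
    register(out_dir / "mr_replication.tsv")
    n_sig = int(mr_disc["significant"].sum()) if len(mr_disc) else 0
    n_rep = int(mr_rep["replicated"].sum()) if len(mr_rep) else 0
    stage("mr", tested=len(mr_disc), untested=len(untested),
          significant=n_sig, replicated=n_rep)

    # ---- regional concordance for significant proteins --------------------
    ld = ld_lookup_from_dosages(dosage_frame)
    verdicts = []
    sig_ids = mr_disc.loc[mr_disc["significant"], "protein_id"].tolist()
    for pid in sig_ids:
        region = scan["regions"][pid]
        exp_stats = scan["associations"]
        exp_stats = exp_stats[exp_stats["protein_id"] == pid]
        try:
            data = region_alignment(exp_stats, study["outcome_discovery"],
                                    region, ld_lookup=ld)
        except ValueError as exc:
            manifest.warnings.append({"stage": "coloc", "protein_id": pid,
                                      "reason": str(exc)})
            continue
        report = lead_concordance(data, ld, r2_concordant=thr.r2_concordant)
        verdicts.append(vars(report))
        if config.make_plots:
            from .plots import mirror_plot
            mirror_plot(data, out_dir / f"mirror_{pid}.png")
    pd.DataFrame(verdicts).to_csv(out_dir / "concordance.tsv", sep="\t", index=False)
    register(out_dir / "concordance.tsv")
    stage("coloc", regions=len(verdicts),
          concordant=sum(v["verdict"] == "concordant_lead" for v in verdicts))

    if config.make_plots and len(mr_disc):
        from .plots import volcano_plot
        volcano_plot(mr_disc, out_dir / "mr_volcano.png", alpha=thr.alpha_mr,
                     title="MR discovery")

    # ---- funnel -----------------------------------------------------------
    manifest.funnel = {
        "assays_measured": npx.n_assays,
        "assays_post_qc": npx_qc.n_assays,
        "proteins_with_cis_pqtl": proteins_with_pqtl,
        "proteins_mr_tested": len(mr_disc),
        "proteins_mr_significant": n_sig,
        "proteins_replicated": n_rep,
    }
    funnel_df = pd.DataFrame([{"stage": k, "count": v}
                              for k, v in manifest.funnel.items()])
    funnel_df.to_csv(out_dir / "funnel.tsv", sep="\t", index=False)
    register(out_dir / "funnel.tsv")

    manifest.finished = time.time()
    mdict = manifest.to_dict()
    mdict_for_file = dict(mdict)
    mdict_for_file.pop("started")
    mdict_for_file.pop("finished")
    io.write_json(mdict_for_file, out_dir / "manifest.json")
    return manifest
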