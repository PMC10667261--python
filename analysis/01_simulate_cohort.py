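#!/usr/bin/env python
"""Generate the synthetic study the downstream analyses run on.

One exposure cohort of 598 women (genotypes, NPX proteomics for 50
proteins, baseline covariates) plus two independent case-control outcome
cohorts (10k/10k each) summarised as GWAS statistics.  The scenario is
causal: protein P0001 raises outcome log-odds by 0.3 per NPX SD; the
other 49 proteins have cis-pQTL but no outcome effect.
"""

from pathlib import Path

from pqtlmr import SimulationConfig, simulate_study
from pqtlmr import io

SEED = 2024
OUT = Path("results/data")


def main() -> None:
    cfg = SimulationConfig(n_proteins=50, scenario="causal", theta=0.3,
                           n_causal=1, seed=SEED)
    study = simulate_study(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_dosage_tsv(study["genotypes"], OUT / "dosages.tsv")
    io.write_vcf(study["genotypes"], OUT / "genotypes.vcf")
    io.write_npx_csv(study["npx"], OUT / "npx.csv", OUT / "assays.csv")
    io.write_covariates_tsv(study["covariates"], OUT / "covariates.tsv")
    io.write_gene_annotation(study["npx"].assays, OUT / "genes.tsv")
    io.write_outcome_tsv(study["outcome_discovery"], OUT / "outcome_discovery.tsv")
    io.write_outcome_tsv(study["outcome_replication"], OUT / "outcome_replication.tsv")
    truth = {"config": cfg.to_dict(),
             "causal_proteins": [r["protein_id"] for r in
                                 study["truth"]["proteins"] if r["causal"]],
             "lead_variants": {r["protein_id"]: r["signal_ids"]
                               for r in study["truth"]["proteins"]}}
    io.write_json(truth, OUT / "truth.json")
    geno = study["genotypes"]
    print(f"wrote {geno.n_samples} samples x {geno.n_variants} variants, "
          f"{study['npx'].n_assays} assays to {OUT}")
    print(f"causal protein(s): {truth['causal_proteins']} (theta = {cfg.theta})")


if __name__ == "__main__":
    main()
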