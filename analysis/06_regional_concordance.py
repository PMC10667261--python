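#!/usr/bin/env python
"""Regional concordance of protein and outcome association signals.

For every MR-significant protein, the cis region's exposure and outcome
statistics are joined into mirror-plot data and the lead variants are
compared in LD space: shared or strongly linked leads (r^2 >= 0.8)
support a shared causal variant; weakly linked leads flag possible LD
confounding.
"""

from pathlib import Path

import pandas as pd

from pqtlmr import io
from pqtlmr.coloc import ld_lookup_from_dosages, lead_concordance, region_alignment
from pqtlmr.pqtl import define_cis_region
from pqtlmr.plots import mirror_plot

DATA = Path("results/data")
PQTL = Path("results/pqtl")
MR = Path("results/mr")
OUT = Path("results/coloc")


def main() -> None:
    disc = pd.read_csv(MR / "mr_discovery.tsv", sep="\t")
    assoc = pd.read_csv(PQTL / "cis_associations.tsv", sep="\t",
                        dtype={"chrom": str})
    geno = io.read_dosage_tsv(DATA / "dosages.tsv")
    genes = io.read_gene_annotation(DATA / "genes.tsv")
    outcome = io.read_outcome_tsv(DATA / "outcome_discovery.tsv")
    ld = ld_lookup_from_dosages(geno.dosage_frame())
    OUT.mkdir(parents=True, exist_ok=True)

    verdicts = []
    for pid in disc.loc[disc["significant"], "protein_id"]:
        assay = genes[genes["protein_id"] == pid].iloc[0]
        region = define_cis_region(assay, geno.variants)
        stats = assoc[assoc["protein_id"] == pid]
        data = region_alignment(stats, outcome, region, ld_lookup=ld)
        report = lead_concordance(data, ld)
        verdicts.append(vars(report))
        data.table.to_csv(OUT / f"mirror_{pid}.tsv", sep="\t", index=False)
        mirror_plot(data, OUT / f"mirror_{pid}.png")
        print(f"{pid}: lead pQTL {data.lead_exposure_id}, lead outcome "
              f"{data.lead_outcome_id}, r2 = {report.r2_leads:.2f} "
              f"-> {report.verdict}")
    pd.DataFrame(verdicts).to_csv(OUT / "concordance.tsv", sep="\t", index=False)
    print(f"wrote {len(verdicts)} regional verdicts to {OUT}")


if __name__ == "__main__":
    main()
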