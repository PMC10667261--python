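#!/usr/bin/env python
"""Two-sample Mendelian randomisation of protein levels on the outcome.

Independent cis-pQTL (r^2 < 0.001) instrument each protein.  The Wald
ratio (or fixed-effect IVW for multi-instrument proteins) is screened
against the discovery outcome at p < 7.5e-5; significant proteins are
re-estimated against the independent replication outcome and replicate
at nominal p < 0.05 with a concordant effect direction.
"""

from pathlib import Path

import pandas as pd

from pqtlmr import io
from pqtlmr.mr import clump_instruments, mr_screen, replicate
from pqtlmr.plots import volcano_plot

DATA = Path("results/data")
PQTL = Path("results/pqtl")
OUT = Path("results/mr")


def main() -> None:
    hits = pd.read_csv(PQTL / "pqtl_hits.tsv", sep="\t", dtype={"chrom": str})
    geno = io.read_dosage_tsv(DATA / "dosages.tsv")
    frame = geno.dosage_frame()
    instruments = {}
    for pid, sub in hits.groupby("protein_id", sort=True):
        g = frame[sub["id"].tolist()].to_numpy(dtype=float)
        instruments[pid] = clump_instruments(sub, g, r2_max=0.001)

    disc_outcome = io.read_outcome_tsv(DATA / "outcome_discovery.tsv")
    disc, untested = mr_screen(instruments, disc_outcome,
                               alpha_discovery=7.5e-5, outcome_id="discovery")
    OUT.mkdir(parents=True, exist_ok=True)
    disc.to_csv(OUT / "mr_discovery.tsv", sep="\t", index=False)
    io.write_json({"untested": untested}, OUT / "mr_untested.json")
    volcano_plot(disc, OUT / "mr_volcano.png", alpha=7.5e-5,
                 title="MR discovery screen")

    print(f"{len(disc)} proteins tested, {len(untested)} untested "
          "(no harmonisable instrument in the outcome)")
    sig = disc[disc["significant"]]
    print(f"{len(sig)} proteins pass discovery at p < 7.5e-5:")
    for _, row in sig.iterrows():
        print(f"  {row['protein_id']}: nsnp={row['nsnp']} "
              f"beta={row['beta']:+.3f} p={row['p']:.2e}")

    rep_outcome = io.read_outcome_tsv(DATA / "outcome_replication.tsv")
    rep = replicate(disc, instruments, rep_outcome, alpha_rep=0.05)
    rep.to_csv(OUT / "mr_replication.tsv", sep="\t", index=False)
    for _, row in rep.iterrows():
        status = "REPLICATED" if row["replicated"] else "not replicated"
        print(f"  replication {row['protein_id']}: beta={row['beta']:+.3f} "
              f"p={row['p']:.2e} -> {status}")
    truth = io.read_json(DATA / "truth.json")
    print(f"simulated causal protein(s): {truth['causal_proteins']}")


if __name__ == "__main__":
    main()
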