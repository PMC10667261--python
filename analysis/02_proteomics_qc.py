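#!/usr/bin/env python
"""Proteomics quality control of the simulated NPX data.

Computes per-assay detectability against the limit of detection, drops
assays with detectability <= 25%, and screens samples for PCA outliers
(|z| > 5 on the first two components).  Sub-LOD values in retained
assays stay in the data.
"""

from pathlib import Path

from pqtlmr import io, run_qc

DATA = Path("results/data")
OUT = Path("results/qc")


def main() -> None:
    npx = io.read_npx_csv(DATA / "npx.csv", DATA / "assays.csv")
    filtered, report = run_qc(npx, min_detect=0.25)
    OUT.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(OUT / "detectability.tsv", sep="\t", index=False)
    io.write_json({"excluded_samples": report.excluded_samples,
                   "excluded_assays": report.excluded_assays},
                  OUT / "qc_report.json")
    io.write_npx_csv(filtered, OUT / "npx_qc.csv", OUT / "assays_qc.csv")
    det = report.detectability
    print(f"detectability: median {det.median():.2f}, "
          f"min {det.min():.2f}, max {det.max():.2f}")
    print(f"kept {filtered.n_assays}/{npx.n_assays} assays; "
          f"excluded {len(report.excluded_samples)} samples "
          f"({len(report.excluded_assays)} assays below the detectability floor)")


if __name__ == "__main__":
    main()
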