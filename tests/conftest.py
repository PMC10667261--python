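import numpy as np
import pandas as pd
import pytest

from pqtlmr import SimulationConfig, simulate_study
from pqtlmr.simulate import NPXMatrix


def make_npx(values, lods, sample_ids=None, chrom="1", gene_start=2_000_000,
             panel="ExploreI") -> NPXMatrix:
    """Hand-built NPX container for fixture-driven QC tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    lods = np.asarray(lods, dtype=float)
    assays = pd.DataFrame({
        "protein_id": [f"P{j + 1:04d}" for j in range(p)],
        "gene": [f"GENE{j + 1:04d}" for j in range(p)],
        "chrom": chrom,
        "gene_start": gene_start,
        "gene_end": gene_start + 10_000,
        "panel": panel,
        "lod": lods,
    })
    if sample_ids is None:
        sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    below = values < lods[None, :]
    return NPXMatrix(values=values, sample_ids=list(sample_ids), assays=assays,
                     below_lod=below)


@pytest.fixture(scope="session")
def causal_study():
    """One moderate causal study shared by read-only tests."""
    cfg = SimulationConfig(n_proteins=12, n_samples=598, scenario="causal",
                           theta=0.3, n_cases=8000, n_controls=8000, seed=11)
    return simulate_study(cfg)
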