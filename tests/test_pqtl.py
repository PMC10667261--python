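"""Cis-region definition, association scan, independence counting and
pQTL selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pqtlmr import SimulationConfig, simulate_covariates, simulate_genotypes, simulate_npx
from pqtlmr.pqtl import (
    cis_scan,
    count_independent,
    define_cis_region,
    pqtl_scan_all,
    select_pqtl,
    significance_threshold,
)


def _toy_variants(positions, chrom="1"):
    return pd.DataFrame({
        "id": [f"v{i}" for i in range(len(positions))],
        "chrom": chrom,
        "pos": positions,
        "effect_allele": "A",
        "other_allele": "G",
        "maf": 0.3,
        "region": 0,
    })


def _assay(chrom="1", start=2_000_000, end=2_010_000):
    return pd.Series({"protein_id": "P0001", "chrom": chrom,
                      "gene_start": start, "gene_end": end})


class TestCisRegion:
    def test_window_boundaries_inclusive(self):
        variants = _toy_variants([999_999, 1_000_000, 3_010_000, 3_010_001])
        region = define_cis_region(_assay(), variants, window=1_000_000)
        assert region.variant_ids == ["v1", "v2"]  # 1,000,000 in; 999,999 out
        assert region.window_start == 1_000_000
        assert region.window_end == 3_010_000

    def test_window_clipped_at_one(self):
        variants = _toy_variants([1, 100])
        region = define_cis_region(_assay(start=5000, end=6000), variants)
        assert region.window_start == 1

    def test_membership_matches_bruteforce(self):
        rng = np.random.default_rng(12)
        positions = np.sort(rng.integers(1, 5_000_000, size=20))
        variants = _toy_variants(positions)
        region = define_cis_region(_assay(), variants)
        expected = [f"v{i}" for i, p in enumerate(positions)
                    if 1_000_000 <= p <= 3_010_000]
        assert region.variant_ids == expected

    def test_wrong_chromosome_excluded(self):
        variants = _toy_variants([2_000_000], chrom="2")
        region = define_cis_region(_assay(chrom="1"), variants)
        assert region.n_variants == 0

    def test_missing_coordinates_raise(self):
        assay = pd.Series({"protein_id": "P1", "chrom": "1",
                           "gene_start": np.nan, "gene_end": 10})
        with pytest.raises(ValueError, match="gene_start"):
            define_cis_region(assay, _toy_variants([100]))


@pytest.fixture(scope="module")
def scan_setup():
    cfg = SimulationConfig(n_samples=598, n_proteins=1, variants_per_region=30,
                           cis_h2=0.0, covariate_effects={}, seed=81)
    geno = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg)
    return cfg, geno, cov


class TestCisScan:
    def test_recovers_simulated_effect(self, scan_setup):
        cfg, geno, cov = scan_setup
        assay = geno.variants.iloc[0]
        region = define_cis_region(
            pd.Series({"protein_id": "P0001", "chrom": assay["chrom"],
                       "gene_start": int(geno.variants["pos"].iloc[15]) - 5000,
                       "gene_end": int(geno.variants["pos"].iloc[15]) + 5000}),
            geno.variants)
        rng = np.random.default_rng(5)
        g = geno.dosages[:, 15].astype(float)
        y = 0.4 * g + 0.05 * rng.standard_normal(598)
        res = cis_scan(y, geno, cov, region, standardise=False)
        row = res[res["id"] == geno.variants["id"].iloc[15]].iloc[0]
        half = stats.t.ppf(0.975, 598 - 14) * row["se"]
        assert abs(row["beta"] - 0.4) <= half

    def test_null_p_values_uniform(self):
        cfg = SimulationConfig(n_samples=400, n_proteins=10, variants_per_region=20,
                               ld_rho=0.0, cis_h2=0.0, covariate_effects={}, seed=82)
        geno = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg)
        npx = simulate_npx(geno, cov, cfg)
        p_all = []
        for j in range(10):
            assay = npx.assays.iloc[j]
            region = define_cis_region(assay, geno.variants)
            res = cis_scan(npx.values[:, j], geno, cov, region)
            p_all.extend(res["p"].tolist())
        assert stats.kstest(p_all, "uniform").pvalue > 0.01

    def test_allele_coding_symmetry(self, scan_setup):
        cfg, geno, cov = scan_setup
        npx = simulate_npx(geno, cov, cfg)
        assay = npx.assays.iloc[0]
        region = define_cis_region(assay, geno.variants)
        res1 = cis_scan(npx.values[:, 0], geno, cov, region)
        flipped = simulate_genotypes(cfg)
        flipped.dosages = (2 - flipped.dosages.astype(int)).astype(np.uint8)
        res2 = cis_scan(npx.values[:, 0], flipped, cov, region)
        assert np.allclose(res1["beta"], -res2["beta"], atol=1e-10)
        assert np.allclose(res1["p"], res2["p"], atol=1e-12)

    def test_maf_filter_drops_rare_variants(self, scan_setup):
        cfg, geno, cov = scan_setup
        assay = pd.Series({"protein_id": "P0001", "chrom": "1",
                           "gene_start": int(geno.variants["pos"].min()),
                           "gene_end": int(geno.variants["pos"].max())})
        region = define_cis_region(assay, geno.variants)
        res = cis_scan(np.random.default_rng(0).normal(size=598), geno, cov,
                       region, maf_min=0.2)
        eaf = res["eaf"].to_numpy()
        assert (np.minimum(eaf, 1 - eaf) >= 0.2).all()
        assert len(res) < region.n_variants


def _greedy_oracle(g, r2_max, order):
    """Independent re-implementation of greedy pruning for the oracle."""
    kept = []
    for j in order:
        ok = True
        for k in kept:
            r = np.corrcoef(g[:, j], g[:, k])[0, 1]
            if r * r >= r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept


class TestCountIndependent:
    def test_mutually_independent_variants(self):
        g = np.random.default_rng(1).binomial(2, 0.4, size=(500, 5)).astype(float)
        assert count_independent(g, 0.1) == 5

    def test_duplicate_counted_once(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.4, size=(300, 1)).astype(float)
        g = np.column_stack([g, g])
        assert count_independent(g, 0.1) == 1

    def test_single_variant(self):
        g = np.random.default_rng(3).binomial(2, 0.3, size=(100, 1)).astype(float)
        assert count_independent(g) == 1

    def test_block_fixture_matches_oracle(self):
        cfg = SimulationConfig(n_samples=800, n_proteins=1, variants_per_region=12,
                               ld_rho=0.85, seed=84)
        g = simulate_genotypes(cfg).dosages.astype(float)
        expected = len(_greedy_oracle(g, 0.1, range(12)))
        assert count_independent(g, 0.1) == expected

    def test_invariant_to_duplicating_kept_variant(self):
        cfg = SimulationConfig(n_samples=500, n_proteins=1, variants_per_region=8,
                               ld_rho=0.7, seed=85)
        g = simulate_genotypes(cfg).dosages.astype(float)
        base = count_independent(g, 0.1)
        dup = np.column_stack([g, g[:, [0]]])
        assert count_independent(dup, 0.1) == base


class TestSignificanceThreshold:
    def test_published_mean_gives_published_threshold(self):
        assert significance_threshold(180, 0.05) == pytest.approx(2.77e-4, abs=1e-6)

    def test_identity_at_one(self):
        assert significance_threshold(1) == 0.05

    def test_max_independent_count(self):
        assert significance_threshold(511) == pytest.approx(9.78e-5, abs=1e-7)

    def test_sub_one_mean_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold(0.5)


class TestSelectPqtl:
    def _results(self, geno, p_vals):
        v = geno.variants
        return pd.DataFrame({
            "id": v["id"], "chrom": v["chrom"], "pos": v["pos"],
            "effect_allele": v["effect_allele"], "other_allele": v["other_allele"],
            "protein_id": "P0001", "eaf": v["maf"],
            "beta": 0.1, "se": 0.02, "p": p_vals, "n": geno.n_samples,
            "ok": True,
        })

    def test_single_significant_hit(self):
        cfg = SimulationConfig(n_samples=300, n_proteins=1, variants_per_region=5,
                               ld_rho=0.0, seed=86)
        geno = simulate_genotypes(cfg)
        p = np.array([0.5, 1e-6, 0.3, 0.9, 0.8])
        hits = select_pqtl(self._results(geno, p), 2.77e-4,
                           geno.dosages.astype(float))
        assert len(hits) == 1 and hits["rank"].iloc[0] == 1
        assert hits["id"].iloc[0] == geno.variants["id"].iloc[1]

    def test_correlated_pair_clumps_to_smaller_p(self):
        rng = np.random.default_rng(87)
        a = rng.binomial(2, 0.4, size=600).astype(float)
        noise = rng.binomial(1, 0.25, size=600)
        b = np.clip(a + noise - rng.binomial(1, 0.25, size=600), 0, 2)  # r2 ~ 0.5
        g = np.column_stack([a, b])
        assert np.corrcoef(a, b)[0, 1] ** 2 > 0.1
        res = pd.DataFrame({"id": ["v0", "v1"], "chrom": "1", "pos": [100, 200],
                            "effect_allele": "A", "other_allele": "G",
                            "protein_id": "P", "eaf": 0.4, "beta": 0.1,
                            "se": 0.02, "p": [1e-5, 1e-8], "n": 600, "ok": True})
        hits = select_pqtl(res, 1e-3, g)
        assert hits["id"].tolist() == ["v1"]

    def test_no_significant_variant_returns_empty(self):
        cfg = SimulationConfig(n_samples=200, n_proteins=1, variants_per_region=4,
                               seed=88)
        geno = simulate_genotypes(cfg)
        hits = select_pqtl(self._results(geno, np.full(4, 0.5)), 1e-4,
                           geno.dosages.astype(float))
        assert len(hits) == 0

    def test_pairwise_r2_of_hits_below_threshold(self):
        cfg = SimulationConfig(n_samples=700, n_proteins=1, variants_per_region=25,
                               ld_rho=0.9, seed=89)
        geno = simulate_genotypes(cfg)
        rng = np.random.default_rng(0)
        p = 10.0 ** (-rng.uniform(2, 9, size=25))
        g = geno.dosages.astype(float)
        hits = select_pqtl(self._results(geno, p), 1e-1, g)
        ids = {vid: j for j, vid in enumerate(geno.variants["id"])}
        cols = [ids[v] for v in hits["id"]]
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                r = np.corrcoef(g[:, cols[a]], g[:, cols[b]])[0, 1]
                assert r * r < 0.1

    def test_lead_hit_tracks_causal_variant(self):
        """With a genuine cis signal the selected lead is the causal
        variant or a close LD proxy in >=90% of replicates."""
        good = 0
        n_rep = 200
        for rep in range(n_rep):
            cfg = SimulationConfig(n_samples=598, n_proteins=1,
                                   variants_per_region=30, cis_h2=0.1,
                                   covariate_effects={}, seed=20_000 + rep)
            geno = simulate_genotypes(cfg)
            cov = simulate_covariates(cfg)
            npx = simulate_npx(geno, cov, cfg)
            truth = npx.truth["proteins"][0]
            region = define_cis_region(npx.assays.iloc[0], geno.variants)
            res = cis_scan(npx.values[:, 0], geno, cov, region)
            ids = {vid: j for j, vid in enumerate(geno.variants["id"])}
            g = geno.dosages[:, [ids[v] for v in res["id"]]].astype(float)
            hits = select_pqtl(res, 2.77e-4, g)
            if len(hits) == 0:
                continue
            lead_id = hits.sort_values("rank")["id"].iloc[0]
            causal_id = truth["signal_ids"][0]
            if lead_id == causal_id:
                good += 1
            else:
                a = geno.dosages[:, ids[lead_id]].astype(float)
                b = geno.dosages[:, ids[causal_id]].astype(float)
                good += np.corrcoef(a, b)[0, 1] ** 2 > 0.5
        assert good / n_rep >= 0.90


class TestScanAll:
    def test_null_familywise_rate_controlled(self):
        cfg = SimulationConfig(n_samples=400, n_proteins=60, variants_per_region=15,
                               cis_h2=0.0, covariate_effects={}, seed=90)
        geno = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg)
        npx = simulate_npx(geno, cov, cfg)
        scan = pqtl_scan_all(npx, geno, cov, alpha_fixed=2.77e-4)
        n_hit_proteins = scan["hits"]["protein_id"].nunique() if len(scan["hits"]) else 0
        frac = n_hit_proteins / 60
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)

    def test_threshold_derived_from_mean_independent(self, causal_study):
        study = causal_study
        scan = pqtl_scan_all(study["npx"], study["genotypes"], study["covariates"])
        mean_ind = scan["region_summary"]["n_independent"].mean()
        assert scan["threshold"] == pytest.approx(0.05 / mean_ind)
        assert (scan["region_summary"]["n_independent"]
                <= scan["region_summary"]["n_variants"]).all()
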