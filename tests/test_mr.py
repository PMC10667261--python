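"""Instrument clumping, harmonisation, Wald/IVW estimation, screening
and replication logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pqtlmr import SimulationConfig, simulate_study
from pqtlmr.mr import (
    HarmonisedPair,
    Instrument,
    clump_instruments,
    harmonise,
    harmonise_all,
    ivw,
    mr_screen,
    replicate,
    wald_ratio,
)
from pqtlmr.pipeline import analyse_study


def _instr(beta_exp=0.5, se_exp=0.05, ea="A", oa="G", eaf=0.3, pos=100,
           vid="v1", pid="P0001"):
    return Instrument(protein_id=pid, variant_id=vid, chrom="1", pos=pos,
                      effect_allele=ea, other_allele=oa, eaf=eaf,
                      beta_exp=beta_exp, se_exp=se_exp)


def _outcome_row(vid="v1", pos=100, ea="A", oa="G", eaf=0.3, beta=0.05,
                 se=0.01, p=1e-6):
    return pd.DataFrame([{"chrom": "1", "pos": pos, "id": vid,
                          "effect_allele": ea, "other_allele": oa, "eaf": eaf,
                          "beta": beta, "se": se, "p": p,
                          "n_case": 1000, "n_control": 1000}])


def _pair(beta_exp, beta_out, se_out, **kw):
    return HarmonisedPair(_instr(beta_exp=beta_exp, **kw), beta_out, se_out,
                          0.3, "unchanged")


class TestClumpInstruments:
    def _hits(self, ids, p_vals, positions=None):
        k = len(ids)
        return pd.DataFrame({
            "protein_id": "P0001", "id": ids, "chrom": "1",
            "pos": positions or list(range(100, 100 + k)),
            "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
            "beta": 0.4, "se": 0.05, "p": p_vals,
        })

    def test_single_hit_single_instrument(self):
        g = np.random.default_rng(0).binomial(2, 0.3, size=(200, 1)).astype(float)
        out = clump_instruments(self._hits(["v1"], [1e-8]), g)
        assert len(out) == 1 and out[0].variant_id == "v1"

    def test_weak_ld_still_collapses_at_strict_threshold(self):
        """r^2 = 0.05 exceeds the 0.001 instrument threshold, so only the
        more significant hit survives."""
        rng = np.random.default_rng(1)
        n = 20_000
        a = rng.binomial(2, 0.3, size=n).astype(float)
        flip = rng.random(n) < 0.38
        b = np.where(flip, rng.binomial(2, 0.3, size=n), a).astype(float)
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        assert 0.01 < r2 < 0.9
        out = clump_instruments(self._hits(["v1", "v2"], [1e-6, 1e-9]),
                                np.column_stack([a, b]), r2_max=0.001)
        assert [i.variant_id for i in out] == ["v2"]

    def test_fixture_matches_bruteforce_oracle(self):
        cfg = SimulationConfig(n_samples=900, n_proteins=1, variants_per_region=6,
                               ld_rho=0.6, seed=71)
        from pqtlmr.simulate import simulate_genotypes
        g = simulate_genotypes(cfg).dosages.astype(float)
        p_vals = [1e-5, 1e-9, 1e-7, 1e-4, 1e-8, 1e-6]
        hits = self._hits([f"v{i}" for i in range(6)], p_vals)
        out = clump_instruments(hits, g, r2_max=0.001)
        # oracle: greedy by ascending p over the empirical r2 matrix
        order = np.argsort(p_vals)
        r = np.corrcoef(g.T) ** 2
        kept = []
        for j in order:
            if all(r[j, k] < 0.001 for k in kept):
                kept.append(j)
        assert [i.variant_id for i in out] == [f"v{j}" for j in kept]

    def test_empty_input(self):
        assert clump_instruments(self._hits([], []), np.empty((10, 0))) == []


class TestHarmonise:
    def test_identical_alleles_unchanged(self):
        pair = harmonise(_instr(), _outcome_row(beta=0.05))
        assert pair.action == "unchanged"
        assert pair.beta_out == pytest.approx(0.05)

    def test_swapped_alleles_flip_sign(self):
        pair = harmonise(_instr(ea="A", oa="G"),
                         _outcome_row(ea="G", oa="A", beta=0.05, eaf=0.7))
        assert pair.action == "flipped"
        assert pair.beta_out == pytest.approx(-0.05)
        assert pair.eaf_out == pytest.approx(0.3)

    def test_palindromic_alignable_by_eaf(self):
        pair = harmonise(_instr(ea="A", oa="T", eaf=0.10),
                         _outcome_row(ea="A", oa="T", eaf=0.12, beta=0.02))
        assert pair.action == "unchanged"

    def test_palindromic_ambiguous_dropped(self):
        pair = harmonise(_instr(ea="A", oa="T", eaf=0.45),
                         _outcome_row(ea="A", oa="T", eaf=0.48))
        assert pair.action == "dropped_palindromic"

    def test_palindromic_discordant_sides_dropped(self):
        pair = harmonise(_instr(ea="C", oa="G", eaf=0.10),
                         _outcome_row(ea="C", oa="G", eaf=0.90))
        assert pair.action == "dropped_palindromic"

    def test_allele_set_mismatch_dropped(self):
        pair = harmonise(_instr(ea="A", oa="G"), _outcome_row(ea="A", oa="C"))
        assert pair.action == "dropped_mismatch"

    def test_absent_variant_missing(self):
        pair = harmonise(_instr(vid="nope", pos=999), _outcome_row())
        assert pair.action == "missing"
        assert not pair.usable

    def test_match_on_position_despite_id_difference(self):
        pair = harmonise(_instr(vid="rsA", pos=100),
                         _outcome_row(vid="chr1:100", pos=100))
        assert pair.action == "unchanged"


class TestWaldRatio:
    def test_null_outcome(self):
        res = wald_ratio(_pair(0.5, 0.0, 0.02))
        assert res.beta == 0.0 and res.p == 1.0

    def test_hand_computed_example(self):
        res = wald_ratio(_pair(0.5, 0.1, 0.02))
        assert res.beta == pytest.approx(0.2, rel=1e-12)
        assert res.se == pytest.approx(0.04, rel=1e-12)
        # z = 5; p from the standard-normal survival function
        assert res.p == pytest.approx(2 * stats.norm.sf(5.0), rel=1e-10)
        assert res.p == pytest.approx(5.733e-7, rel=1e-3)

    def test_allele_recoding_invariance(self):
        a = wald_ratio(_pair(0.5, 0.1, 0.02))
        b = wald_ratio(_pair(-0.5, -0.1, 0.02))
        assert a.beta == pytest.approx(b.beta, abs=1e-15)
        assert a.se == pytest.approx(b.se, abs=1e-15)
        assert a.p == pytest.approx(b.p, abs=1e-15)

    def test_negative_exposure_beta_gives_positive_se(self):
        res = wald_ratio(_pair(-0.5, 0.1, 0.02))
        assert res.se > 0 and res.beta == pytest.approx(-0.2)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(_pair(0.0, 0.1, 0.02))

    def test_unusable_pair_rejected(self):
        pair = HarmonisedPair(_instr(), None, None, None, "dropped_palindromic")
        with pytest.raises(ValueError):
            wald_ratio(pair)


class TestIVW:
    def test_singleton_reduces_to_wald_exactly(self):
        pair = _pair(0.43, 0.071, 0.013)
        w = wald_ratio(pair)
        v = ivw([pair])
        assert (v.method, v.nsnp) == ("wald", 1)
        assert v.beta == w.beta and v.se == w.se and v.p == w.p

    def test_two_instrument_hand_computation(self):
        # ratios 0.2 and 0.4, both ratio-SE 0.04
        p1 = _pair(1.0, 0.2, 0.04, vid="v1", pos=1)
        p2 = _pair(1.0, 0.4, 0.04, vid="v2", pos=2)
        res = ivw([p1, p2])
        assert res.method == "ivw" and res.nsnp == 2
        assert res.beta == pytest.approx(0.3, rel=1e-12)
        assert res.se == pytest.approx(0.04 / np.sqrt(2), rel=1e-10)

    def test_duplicated_instrument_shrinks_se(self):
        pair = _pair(1.0, 0.3, 0.05)
        base = ivw([pair])
        k = 4
        rep = ivw([pair] * k)
        assert rep.beta == pytest.approx(base.beta, rel=1e-12)
        assert rep.se == pytest.approx(base.se / np.sqrt(k), rel=1e-10)

    def test_all_pairs_dropped_raises(self):
        bad = HarmonisedPair(_instr(), None, None, None, "dropped_mismatch")
        with pytest.raises(ValueError, match="no usable instrument"):
            ivw([bad])


class TestScreenAndReplicate:
    def test_untested_proteins_reported_separately(self):
        instruments = {
            "P0001": [_instr(pid="P0001")],
            "P0002": [_instr(pid="P0002", vid="v9", pos=900)],  # absent from outcome
        }
        table, untested = mr_screen(instruments, _outcome_row(), alpha_discovery=0.05)
        assert table["protein_id"].tolist() == ["P0001"]
        assert untested == [{"protein_id": "P0002", "reason": "missing"}]

    def test_replication_requires_same_sign(self):
        disc = pd.DataFrame([{"protein_id": "P0001", "outcome_id": "discovery",
                              "method": "wald", "nsnp": 1, "beta": 0.2,
                              "se": 0.04, "p": 1e-6, "q_het": None,
                              "significant": True, "replicated": None}])
        instruments = {"P0001": [_instr()]}
        rep_same = replicate(disc, instruments,
                             _outcome_row(beta=0.05, se=0.023), alpha_rep=0.05)
        assert bool(rep_same["replicated"].iloc[0])  # p ~ 0.03, same sign
        rep_opp = replicate(disc, instruments,
                            _outcome_row(beta=-0.05, se=0.023), alpha_rep=0.05)
        assert not bool(rep_opp["replicated"].iloc[0])

    def test_missing_replication_instrument_reported_unreplicable(self):
        disc = pd.DataFrame([{"protein_id": "P0001", "outcome_id": "discovery",
                              "method": "wald", "nsnp": 1, "beta": 0.2,
                              "se": 0.04, "p": 1e-6, "q_het": None,
                              "significant": True, "replicated": None}])
        rep = replicate(disc, {"P0001": [_instr(vid="v9", pos=900)]},
                        _outcome_row())
        assert not bool(rep["replicated"].iloc[0])
        assert rep["note"].iloc[0] == "instrument unavailable"

    def test_screen_accepts_any_outcome_summary(self, causal_study):
        """Subtype/risk-factor generality: the same instruments screen
        against two different outcome summary sets without code change."""
        res = analyse_study(causal_study)
        t1, _ = mr_screen(res["instruments"], causal_study["outcome_discovery"])
        t2, _ = mr_screen(res["instruments"], causal_study["outcome_replication"],
                          outcome_id="other")
        assert len(t1) > 0 and len(t2) > 0
        assert set(t2["protein_id"]) <= set(res["instruments"])
        assert set(t2["outcome_id"]) == {"other"}

    def test_full_mr_allele_recoding_invariance(self, causal_study):
        """Recoding every variant's effect allele in the outcome leaves
        every MR estimate unchanged to 1e-12."""
        res = analyse_study(causal_study)
        out = causal_study["outcome_discovery"].copy()
        recoded = out.copy()
        recoded[["effect_allele", "other_allele"]] = \
            recoded[["other_allele", "effect_allele"]].to_numpy()
        recoded["beta"] = -recoded["beta"]
        recoded["eaf"] = 1.0 - recoded["eaf"]
        t1, u1 = mr_screen(res["instruments"], out)
        t2, u2 = mr_screen(res["instruments"], recoded)
        assert u1 == u2
        merged = t1.merge(t2, on="protein_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["beta_a"], merged["beta_b"], atol=1e-12)
        assert np.allclose(merged["se_a"], merged["se_b"], atol=1e-12)
        assert np.allclose(merged["p_a"], merged["p_b"], atol=1e-12)


class TestMultiInstrument:
    def test_two_signal_simulation_yields_multi_snp_ivw(self):
        cfg = SimulationConfig(n_proteins=4, n_samples=598, variants_per_region=40,
                               n_cis_signals=2, cis_h2=0.2, scenario="causal",
                               theta=0.3, n_cases=20_000, n_controls=20_000,
                               allele_recode_fraction=0.0, seed=72)
        study = simulate_study(cfg)
        res = analyse_study(study)
        assert (res["mr_discovery"]["nsnp"] >= 1).all()
        assert (res["mr_discovery"]["nsnp"] == 2).any()
        ivw_rows = res["mr_discovery"].query("nsnp > 1")
        assert (ivw_rows["method"] == "ivw").all()
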