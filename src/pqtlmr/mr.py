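"""Two-sample Mendelian randomisation of protein levels on a
case-control outcome.

Instruments are independent cis-pQTL (pairwise r^2 < 0.001).  After
harmonising exposure and outcome to a common effect allele, a single
instrument yields the Wald ratio

    beta_MR = beta_outcome / beta_exposure,
    se_MR   = se_outcome / |beta_exposure|,

with the two-sided p-value from the standard-normal tails of
z = beta_MR / se_MR — the first-order SE that ignores exposure
uncertainty.  Multiple instruments combine by fixed-effect
inverse-variance weighting of the per-instrument ratios.  Discovery
significance defaults to p < 7.5e-5; discovery hits are re-estimated
against an independent replication outcome and replicate when p < 0.05
with the same effect direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Instrument", "HarmonisedPair", "MRResult",
    "clump_instruments", "harmonise", "harmonise_all",
    "wald_ratio", "ivw", "mr_screen", "replicate",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class Instrument:
    protein_id: str
    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta_exp: float
    se_exp: float


@dataclass
class HarmonisedPair:
    instrument: Instrument
    beta_out: float | None
    se_out: float | None
    eaf_out: float | None
    action: str  # unchanged | flipped | dropped_palindromic | dropped_mismatch | missing

    @property
    def usable(self) -> bool:
        return self.action in ("unchanged", "flipped")


@dataclass
class MRResult:
    protein_id: str
    outcome_id: str
    method: str          # "wald" | "ivw"
    nsnp: int
    beta: float
    se: float
    p: float
    q_het: float | None = None   # Cochran's Q p-value, diagnostic only
    significant: bool = False
    replicated: bool | None = None

    def as_dict(self) -> dict:
        return {"protein_id": self.protein_id, "outcome_id": self.outcome_id,
                "method": self.method, "nsnp": self.nsnp, "beta": self.beta,
                "se": self.se, "p": self.p, "q_het": self.q_het,
                "significant": self.significant, "replicated": self.replicated}


# ---------------------------------------------------------------------------
# instrument selection


def clump_instruments(hits: pd.DataFrame, region_dosages: np.ndarray,
                      r2_max: float = 0.001) -> list[Instrument]:
    """Greedy p-ordered clumping of one protein's pQTL hits at r^2 < r2_max.

    ``region_dosages`` columns align with ``hits`` rows (reference panel
    for LD).  Near-duplicate signals collapse onto the most significant.
    """
    if len(hits) == 0:
        return []
    g = np.asarray(region_dosages, dtype=float)
    if g.shape[1] != len(hits):
        raise ValueError("dosage columns do not align with hit rows")
    res = hits.reset_index(drop=True)
    order = res.sort_values(["p", "se", "pos"], kind="mergesort").index.to_numpy()
    sd = g.std(axis=0)
    sd[sd <= 0] = np.nan
    gc = (g - g.mean(axis=0)) / sd
    r2 = np.nan_to_num((gc.T @ gc) / g.shape[0]) ** 2
    kept: list[int] = []
    for j in order:
        if all(r2[j, k] < r2_max for k in kept):
            kept.append(int(j))
    return [
        Instrument(
            protein_id=str(res["protein_id"].iloc[j]),
            variant_id=str(res["id"].iloc[j]), chrom=str(res["chrom"].iloc[j]),
            pos=int(res["pos"].iloc[j]),
            effect_allele=str(res["effect_allele"].iloc[j]),
            other_allele=str(res["other_allele"].iloc[j]),
            eaf=float(res["eaf"].iloc[j]),
            beta_exp=float(res["beta"].iloc[j]), se_exp=float(res["se"].iloc[j]),
        )
        for j in kept
    ]


# ---------------------------------------------------------------------------
# harmonisation


def _is_palindromic(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a.upper()) == b.upper()


def _outcome_lookup(outcome: pd.DataFrame) -> dict:
    """Index outcome rows by (chrom, pos, unordered allele pair); variant id
    is kept as a fallback key."""
    idx = {}
    for row in outcome.itertuples(index=False):
        key = (str(row.chrom), int(row.pos),
               frozenset((str(row.effect_allele).upper(), str(row.other_allele).upper())))
        idx[key] = row
        idx.setdefault(("id", str(row.id)), row)
    return idx


def harmonise(instr: Instrument, outcome: pd.DataFrame | dict,
              palindrome_eaf_band: float = 0.42) -> HarmonisedPair:
    """Align one instrument's outcome association to the exposure effect
    allele.

    Swapped allele labels flip the sign and EAF.  Palindromic (A/T, C/G)
    variants are kept only when exposure and outcome EAF lie on the same
    unambiguous side of the frequency band (both below it or both above
    its complement); otherwise the instrument is dropped as
    unresolvable.  Allele sets that match neither orientation are
    dropped as mismatches; absent variants are reported ``missing``.
    """
    lookup = outcome if isinstance(outcome, dict) else _outcome_lookup(outcome)
    ea, oa = instr.effect_allele.upper(), instr.other_allele.upper()
    row = lookup.get((str(instr.chrom), int(instr.pos), frozenset((ea, oa))))
    if row is None:
        row = lookup.get(("id", instr.variant_id))
    if row is None:
        return HarmonisedPair(instr, None, None, None, "missing")
    oea, ooa = str(row.effect_allele).upper(), str(row.other_allele).upper()
    if {oea, ooa} != {ea, oa}:
        return HarmonisedPair(instr, None, None, None, "dropped_mismatch")
    # orient to the exposure effect allele by label first
    if oea == ea:
        beta_out, eaf_out, action = float(row.beta), float(row.eaf), "unchanged"
    else:
        beta_out, eaf_out, action = -float(row.beta), 1.0 - float(row.eaf), "flipped"
    if _is_palindromic(ea, oa):
        # labels cannot resolve strand; the oriented EAF must agree with
        # the exposure EAF on an unambiguous side of the frequency band
        band = palindrome_eaf_band
        same_side = (instr.eaf < band and eaf_out < band) or \
                    (instr.eaf > 1.0 - band and eaf_out > 1.0 - band)
        if not same_side:
            return HarmonisedPair(instr, None, None, None, "dropped_palindromic")
    return HarmonisedPair(instr, beta_out, float(row.se), eaf_out, action)


def harmonise_all(instruments: list[Instrument], outcome: pd.DataFrame,
                  palindrome_eaf_band: float = 0.42) -> list[HarmonisedPair]:
    lookup = _outcome_lookup(outcome)
    return [harmonise(i, lookup, palindrome_eaf_band) for i in instruments]


# ---------------------------------------------------------------------------
# estimators


def wald_ratio(pair: HarmonisedPair, outcome_id: str = "outcome") -> MRResult:
    """Single-instrument causal estimate (see module docstring)."""
    if not pair.usable:
        raise ValueError(f"cannot estimate from a {pair.action} pair")
    b_exp = pair.instrument.beta_exp
    if b_exp == 0:
        raise ZeroDivisionError("exposure beta is zero; Wald ratio undefined")
    beta = pair.beta_out / b_exp
    se = pair.se_out / abs(b_exp)
    z = beta / se
    p = min(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny), 1.0)
    return MRResult(protein_id=pair.instrument.protein_id, outcome_id=outcome_id,
                    method="wald", nsnp=1, beta=beta, se=se, p=p)


def ivw(pairs: list[HarmonisedPair], outcome_id: str = "outcome") -> MRResult:
    """Fixed-effect inverse-variance-weighted combination of Wald ratios.

    A single usable pair reduces exactly to the Wald ratio.  Cochran's Q
    is attached as a heterogeneity diagnostic (never used for
    inference).
    """
    usable = [p for p in pairs if p.usable]
    if not usable:
        raise ValueError("no usable instrument after harmonisation")
    singles = [wald_ratio(p, outcome_id) for p in usable]
    if len(singles) == 1:
        return singles[0]
    b = np.array([s.beta for s in singles])
    w = np.array([1.0 / s.se**2 for s in singles])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = min(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny), 1.0)
    q = float(np.sum(w * (b - beta) ** 2))
    q_p = float(stats.chi2.sf(q, df=len(singles) - 1))
    return MRResult(protein_id=usable[0].instrument.protein_id,
                    outcome_id=outcome_id, method="ivw", nsnp=len(singles),
                    beta=beta, se=se, p=p, q_het=q_p)


# ---------------------------------------------------------------------------
# screening and replication


def mr_screen(instruments_by_protein: dict[str, list[Instrument]],
              outcome: pd.DataFrame, alpha_discovery: float = 7.5e-5,
              outcome_id: str = "outcome",
              palindrome_eaf_band: float = 0.42) -> tuple[pd.DataFrame, list[dict]]:
    """One MR estimate per protein plus an accounting of untested proteins.

    Proteins whose instruments are all missing from (or unharmonisable
    with) the outcome are reported separately as untested — they are not
    non-significant results.
    """
    results, untested = [], []
    lookup = _outcome_lookup(outcome)
    for pid, instruments in instruments_by_protein.items():
        pairs = [harmonise(i, lookup, palindrome_eaf_band) for i in instruments]
        usable = [p for p in pairs if p.usable]
        if not usable:
            reasons = sorted({p.action for p in pairs}) or ["no_instrument"]
            untested.append({"protein_id": pid, "reason": ",".join(reasons)})
            continue
        res = ivw(usable, outcome_id=outcome_id)
        res.significant = res.p < alpha_discovery
        results.append(res)
    table = pd.DataFrame([r.as_dict() for r in results]) if results else \
        pd.DataFrame(columns=["protein_id", "outcome_id", "method", "nsnp",
                              "beta", "se", "p", "q_het", "significant", "replicated"])
    return table, untested


def replicate(discovery: pd.DataFrame,
              instruments_by_protein: dict[str, list[Instrument]],
              replication_outcome: pd.DataFrame, alpha_rep: float = 0.05,
              outcome_id: str = "replication",
              palindrome_eaf_band: float = 0.42) -> pd.DataFrame:
    """Re-estimate each significant discovery hit against an independent
    outcome; a hit replicates iff p < alpha_rep with a concordant sign."""
    hits = discovery[discovery["significant"]].copy()
    rows = []
    lookup = _outcome_lookup(replication_outcome)
    for row in hits.itertuples(index=False):
        instruments = instruments_by_protein.get(row.protein_id, [])
        pairs = [harmonise(i, lookup, palindrome_eaf_band) for i in instruments]
        usable = [p for p in pairs if p.usable]
        if not usable:
            rows.append({"protein_id": row.protein_id, "outcome_id": outcome_id,
                         "method": None, "nsnp": 0, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "beta_discovery": row.beta,
                         "replicated": False, "note": "instrument unavailable"})
            continue
        res = ivw(usable, outcome_id=outcome_id)
        ok = bool(res.p < alpha_rep and np.sign(res.beta) == np.sign(row.beta))
        rows.append({"protein_id": row.protein_id, "outcome_id": outcome_id,
                     "method": res.method, "nsnp": res.nsnp, "beta": res.beta,
                     "se": res.se, "p": res.p, "beta_discovery": row.beta,
                     "replicated": ok, "note": ""})
    return pd.DataFrame(rows, columns=["protein_id", "outcome_id", "method",
                                       "nsnp", "beta", "se", "p",
                                       "beta_discovery", "replicated", "note"])
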