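"""Simulation and pipeline configuration objects with validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

SCENARIOS = ("null", "causal", "ld_confounded")


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass
class SimulationConfig:
    """Generating parameters for the synthetic cohort.

    The defaults emulate the study design the pipeline targets: an
    exposure cohort of 598 women with NPX proteomics and genotypes, and
    two independent case-control outcome cohorts (discovery and
    replication) summarised as GWAS statistics.

    Parameters
    ----------
    n_samples : exposure-cohort size.
    n_proteins : number of assayed proteins, one cis region each.
    variants_per_region : variants simulated per cis region.
    ld_rho : AR(1) correlation of the latent Gaussian between adjacent
        variants (haplotype-level); 0 gives linkage equilibrium.
    maf_range : (low, high) bounds for per-variant minor allele
        frequencies, drawn uniformly.
    cis_h2 : fraction of NPX variance explained by the cis signal.
    covariate_effects : covariate name -> effect in NPX SD units applied
        to the standardised covariate.
    lod_quantile : per-protein fraction of values falling below the
        limit of detection (values are kept but flagged).
    theta : causal effect of the protein on outcome log-odds per NPX SD
        (applies to the first ``n_causal`` proteins under ``causal``).
    n_cases, n_controls : target outcome cohort composition (each of the
        discovery and replication cohorts).
    scenario : ``null`` (no protein-outcome effect), ``causal``, or
        ``ld_confounded`` (a direct variant effect on the outcome in LD
        with the lead pQTL while the protein path is null).
    n_causal : number of proteins carrying the causal / confounded signal.
    n_cis_signals : 1 or 2 independent cis effects per protein (2 splits
        cis_h2 equally between two distant variants, for multi-instrument
        estimation).
    case_effects : protein index -> NPX shift in incident cases (exposure
        cohort only), for observational case-control association tests.
    confound_log_or : direct variant -> outcome log-OR used by the
        ``ld_confounded`` scenario.
    confound_target_r2 : LD (r^2) between the confounding variant and the
        lead pQTL; the closest available variant is chosen.
    allele_recode_fraction : fraction of outcome-summary variants emitted
        with swapped effect/other allele labels (sign and EAF flipped
        consistently) so harmonisation is exercised downstream.
    seed : master seed; every random stream derives from it.
    """

    n_samples: int = 598
    n_proteins: int = 50
    variants_per_region: int = 20
    ld_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    cis_h2: float = 0.1
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.2, "bmi": 0.15}
    )
    lod_quantile: float = 0.1
    theta: float = 0.0
    n_cases: int = 10_000
    n_controls: int = 10_000
    scenario: str = "null"
    n_causal: int = 1
    n_cis_signals: int = 1
    case_effects: Mapping[int, float] = field(default_factory=dict)
    confound_log_or: float = 0.15
    confound_target_r2: float = 0.3
    allele_recode_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_proteins", "variants_per_region", "n_cases", "n_controls"):
            _require(int(getattr(self, name)) > 0, name, "must be a positive count")
        _require(0.0 <= self.ld_rho < 1.0, "ld_rho", "must be in [0, 1)")
        lo, hi = self.maf_range
        _require(0.0 < lo <= hi <= 0.5, "maf_range", "must satisfy 0 < low <= high <= 0.5")
        _require(0.0 <= self.cis_h2 < 1.0, "cis_h2", "must be in [0, 1)")
        _require(0.0 <= self.lod_quantile < 1.0, "lod_quantile", "must be in [0, 1)")
        _require(self.scenario in SCENARIOS, "scenario", f"must be one of {SCENARIOS}")
        if self.scenario in ("null", "ld_confounded"):
            _require(self.theta == 0.0, "theta",
                     f"scenario={self.scenario!r} forces theta=0 (the protein path is null)")
        _require(self.n_cis_signals in (1, 2), "n_cis_signals", "must be 1 or 2")
        _require(1 <= self.n_causal <= self.n_proteins, "n_causal",
                 "must be in [1, n_proteins]")
        _require(0.0 <= self.allele_recode_fraction <= 1.0,
                 "allele_recode_fraction", "must be in [0, 1]")
        _require(0.0 < self.confound_target_r2 < 1.0, "confound_target_r2",
                 "must be in (0, 1)")
        ev = sum(e * e for e in self.covariate_effects.values())
        _require(self.cis_h2 + ev < 1.0, "covariate_effects",
                 "cis_h2 + sum of squared covariate effects must be < 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["covariate_effects"] = dict(self.covariate_effects)
        d["case_effects"] = {str(k): v for k, v in dict(self.case_effects).items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "case_effects" in d:
            d["case_effects"] = {int(k): float(v) for k, v in dict(d["case_effects"]).items()}
        return cls(**d)


@dataclass
class Thresholds:
    """Analysis thresholds; defaults follow the published analysis plan."""

    min_detect: float = 0.25          # strict detectability floor for assay inclusion
    maf_min: float = 0.01             # variant MAF filter before the cis scan
    r2_independent: float = 0.1       # independent-variant counting and hit clumping
    r2_clump: float = 0.001           # instrument selection for MR
    alpha_pqtl: float | None = None   # None -> alpha/mean-independent, else fixed
    alpha: float = 0.05               # base alpha for the cis threshold
    alpha_mr: float = 7.5e-5          # MR discovery significance
    alpha_rep: float = 0.05           # nominal replication significance
    r2_proxy: float = 0.8             # proxy lookup floor
    r2_concordant: float = 0.8        # lead-concordance verdict tier
    palindrome_eaf_band: float = 0.42

    def __post_init__(self) -> None:
        for name in ("min_detect", "maf_min", "r2_independent", "r2_clump",
                     "alpha", "alpha_mr", "alpha_rep", "r2_proxy", "r2_concordant"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must be in [0, 1]")
        _require(0.0 < self.palindrome_eaf_band < 0.5, "palindrome_eaf_band",
                 "must be in (0, 0.5)")


@dataclass
class PipelineConfig:
    """End-to-end run configuration: a simulation plus thresholds."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int | None = None           # overrides simulation.seed when given
    out_dir: str = "results/pipeline"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.simulation.seed = int(self.seed)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and not isinstance(d["simulation"], SimulationConfig):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "thresholds" in d and not isinstance(d["thresholds"], Thresholds):
            d["thresholds"] = Thresholds(**d["thresholds"])
        return cls(**d)
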