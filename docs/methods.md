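# Methods

This note documents the models, default parameters and design choices
behind `pqtlmr`, in the spirit of a statistical-software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic study generator

The generator emulates the statistical structure of a proteogenomic MR
study: a genotyped exposure cohort with NPX proteomics, and two
independent case-control outcome cohorts observed only through GWAS
summary statistics.

**Genotypes.** Each protein owns one cis region of
`variants_per_region` variants (default 20) spanning the ±1 Mbp window
around its gene; 22 chromosome labels are recycled with 6 Mbp spacing so
windows never overlap. Haplotypes arise from a latent Gaussian AR(1)
process with correlation `ld_rho` (default 0.9) between adjacent
variants, thresholded at each variant's minor-allele-frequency quantile;
two haplotypes sum to a dosage in {0,1,2}. This Gaussian-copula
threshold model is the simplest mechanism that yields tunable, monotone
r² decay — which is what the pruning, clumping and proxy-lookup
machinery needs — and the empirical adjacent-variant r² is checked in
the tests against an independent Monte-Carlo evaluation of the same
bivariate-normal threshold integral. MAFs are uniform on `maf_range`
(default 0.05–0.5). About 15% of variants get strand-palindromic allele
pairs (A/T, C/G) so harmonisation has real work to do. What is *not*
modelled: realistic human LD maps, imputation uncertainty, relatedness,
population structure, X-chromosome dosage.

**NPX protein levels.** Per protein,
`NPX = offset + β_g·(g − 2f) + Σ_c γ_c·z_c + ε`, with β_g set so the
cis variant explains `cis_h2` of the unit total variance (default 0.1;
a study of this size detects h² ≈ 0.05–0.3 instruments, and 0.1 is the
central value used throughout the operating-characteristic
experiments), standardised covariate effects γ (default: age 0.2, BMI
0.15 NPX SD) and Gaussian noise filling the remainder. With
`n_cis_signals = 2` the cis variance splits equally between two distant
variants to exercise multi-instrument IVW. A per-assay limit of
detection sits at the `lod_quantile` (default 0.1) of the simulated
distribution; sub-LOD values are flagged but retained, because the
analysis convention is to keep them. The covariate table mimics a
middle-aged female screening cohort (age-dependent menopause, balanced
case/control labels); it makes no claim of demographic realism beyond
giving the adjustment machinery plausible inputs.

**Outcomes.** A fresh cohort of `n_cases + n_controls` individuals
(default 10k/10k per outcome) is drawn on the same variant panel. Case
status follows `logit P(y=1) = α + θ·L`, where L is the genetically
regulated protein liability (genetic part plus residual noise of
variance 1 − cis_h2) and α is solved by root-finding so the expected
case fraction matches the design. Under `ld_confounded`, θ = 0 and a
direct variant effect (default log-OR 0.15) is placed on the region
variant whose empirical r² with the lead pQTL is closest to
`confound_target_r2` (default 0.3). Summary statistics come from
per-variant univariate logistic regression fitted by a vectorised
Newton solver (checked against statsmodels in the tests), preserving
the realistic coupling of SE, EAF and sample size; simulating
individuals and then summarising was chosen over fabricating summary
statistics directly for exactly that reason. A deterministic 20% of
emitted variants are re-oriented to the opposite effect allele (sign
and EAF flipped consistently) so the pipeline's harmonisation is
exercised end-to-end, not only in unit tests.

**Determinism.** Every stream derives from the master seed via SHA-256
hashed tags (stage, cohort, region), so outputs are pure functions of
(config, seed), discovery and replication cohorts are independent, and
changing the draw count in one stage never perturbs another.

## Quality control

Detectability is the fraction of non-missing values strictly above the
assay LOD; missing values leave the denominator because an LOD
comparison is undefined for them. Assay inclusion requires
detectability strictly greater than `min_detect` (default 0.25): the
conventions "more than 75% below LOD are excluded" and "more than 25%
detectability are included" are consistent only under strict
inequality, so a tie at the threshold drops. Sample outliers are
flagged by PCA (missing values mean-imputed for the decomposition
only): any sample beyond `z_cut` = 5 SDs on either of the first two
components is excluded. The published workflow names PCA but no numeric
criterion; ±5 SD on two components is this package's documented
stand-in, conservative enough to exclude at most a handful of samples,
and configurable.

## Clinical association models

Each protein is regressed once on seven baseline characteristics —
age, BMI, menopause (two dummy contrasts against pre-menopause),
parity, current HRT vs never/past, weekly alcohol grams, current
smoking vs never/past — giving 8 coefficients in 7 characteristic
families. Continuous covariates enter untransformed. Missing covariates
drop listwise; classical OLS SEs and t p-values are reported. FDR
correction is Benjamini–Hochberg with denominator m = n_proteins × 7 by
default (one slot per characteristic family, the convention of
correcting protein-characteristic pairs); the exact coefficient count
is available via the `m` argument. `fdr_adjust` is hand-written because
the installed multiple-testing routines cannot correct a sub-vector
against a larger family; it is verified against a brute-force
implementation of the step-up definition and against statsmodels when
m equals the vector length. The incident case-control model regresses
NPX on case status adjusted for age, BMI and storage time, judged at
5% FDR.

## Cis-pQTL scan

Regions are 1-based inclusive intervals [gene_start − 1 Mbp,
gene_end + 1 Mbp], clipped at 1. Variants with MAF < 0.01 are removed
before testing. NPX is z-scaled by default so betas are in NPX SD per
effect-allele copy (a flag disables scaling). The per-variant model is
OLS on dosage plus age, BMI and 10 genetic PCs, computed by
Frisch–Waugh residualisation (trait and dosages projected off the
covariate design once, then univariate slopes); the tests assert exact
equality with the full joint model per variant.

Multiple testing follows the independence-aware convention: per region,
count independent variants by greedy *position-order* pruning at
r² < 0.1, then apply one global threshold alpha / mean-count. Counting
in position order (never p-order) keeps the test burden independent of
the association results. Hit selection is separate and *p-ordered*:
take the most significant variant below threshold, discard everything
at r² ≥ 0.1 with it, repeat; ties in p break by lower SE then position,
making selection deterministic. A per-region (rather than global)
threshold is available behind `alpha_fixed`.

## Mendelian randomisation

Instruments are hit-table rows re-clumped at r² < 0.001. Harmonisation
matches variants on chrom:pos plus the unordered allele pair (id as
fallback), orients the outcome to the exposure effect allele by label
(swapped labels negate the beta and complement the EAF), and resolves
palindromic variants by frequency: after label orientation, exposure
and outcome EAF must both lie below the 0.42 band or both above its
complement, otherwise the instrument drops as `dropped_palindromic`.
Applying label orientation *before* the band test makes harmonisation
invariant to allele recoding of either dataset (asserted to 1e-12).
The 0.42 band mirrors common two-sample MR practice and is
configurable; dropping ambiguous palindromes is the package's choice
where the convention is unstated.

The Wald SE uses |β_exp|: the verbal ratio-of-SE formula yields a
negative SE for negative exposure effects, and the absolute value
restores validity without changing |z|. The SE is first-order
(exposure uncertainty ignored), matching standard reporting; it
understates uncertainty for weak instruments, which is why the
recovery experiments run at cis_h2 ≥ 0.05 with large outcome cohorts.
IVW is fixed-effect only; Cochran's Q is attached as a diagnostic and
never used for inference. Proteins whose instruments are all missing
or unharmonisable are reported *untested*, a separate category from
non-significant. Discovery alpha defaults to 7.5×10⁻⁵ (the published
convention for this family size, adopted as given); replication
requires nominal p < 0.05 *and* a concordant sign, so a null protein
that slips through discovery replicates with probability ≈ 0.025.

## Regional concordance

Formal Bayesian colocalisation is out of scope. The mirror-plot data
joins exposure and outcome statistics on the orientation-free variant
key within the cis window; leads are argmin-p per side. The verdict is
an explicit quantitative stand-in for the visual call: identical or
strongly linked leads (r² ≥ 0.8) give `concordant_lead`; moderately
linked leads (r² ≥ 0.1) give `same_limited_region`; otherwise
`discordant`. The tiers are configurable, reported with every verdict,
and never claimed to reproduce anyone's visual judgement. Proxy lookup
returns all panel variants with r² > 0.8 to a query; cross-study
effect-size comparison harmonises signs to a common effect allele
before the Pearson correlation.

## Numerical choices and degenerate inputs

P-values are clipped into (tiny, 1] so downstream −log10 transforms and
the (0,1] contract hold. Zero-variance dosages are flagged and skipped,
not errors; constant NPX yields a flagged degenerate clinical fit
(betas 0, p 1). Rank-deficient clinical designs raise an error naming
the collinear terms via the QR diagonal. The logistic Newton solver
declares non-convergence per variant and flags rather than reports
garbage. Greedy procedures are deterministic under the documented tie
rules. The alpha root-solve uses Brent's method on a ±30 logit
bracket.

## Problem sizes in the experiments

Operating-characteristic experiments use an exposure cohort of 598 (the
emulated study's size) and trim simulation scale to what the question
needs: single-protein replicates use 1–3 variants per region (the
parameter-recovery experiment uses exactly one variant so the mean
estimate isolates the estimator — selecting the maximum association
among correlated neighbours would add a small winner's-curse inflation
of the denominator), null calibration uses 5k/5k outcome cohorts over
1000 replicates, recovery uses 50k/50k over 200, the end-to-end funnel
uses 50 proteins × 50 runs at the 10k/10k default, and LD-confounding
detection uses 30-variant regions over 100 replicates. MAF is
restricted to 0.10–0.40 in single-protein replicates so no replicate is
lost to palindrome ambiguity (keeping replicate counts exact); the
funnel runs use the full default MAF range, so occasional
palindrome-dropped instruments are part of the measured operating
characteristics.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* of a proteogenomic
MR study — LD decay, cis effect sizes, LOD censoring, SE/EAF coupling,
independent discovery/replication cohorts — so passing tests show the
pipeline's estimators, thresholds, exclusion accounting and error rates
behave as designed under that skeleton. They do not show robustness to
features the generator omits: real LD irregularity, assay batch
effects, population stratification beyond the simulated PCs,
horizontal pleiotropy (instruments here affect outcomes only through
the protein or a linked direct effect), or selection effects in cohort
recruitment.
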