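# Methods

## Study design being emulated

The pipeline analyses a nested case-control study of blood DNA methylation
and incident coronary heart disease (CHD): incident cases arising during
cohort follow-up, each matched 1:1 to a control on sex, study area, age
(±3 years) and fasting-time stratum. Methylation is measured on an
Infinium-style array with two probe chemistries (Type I and II) producing
methylated (M) and unmethylated (U) channel intensities per CpG; the
analysis quantity is the beta value β = M/(M+U+100) ∈ [0, 1].

Because the motivating cohort's data are access-restricted, the package
ships a synthetic-data generator whose defaults reproduce the study's
*structure* (matching, covariates, bimodal beta marginals, latent technical
factors, co-methylation modules, mediation pathways) at desk scale
(hundreds of samples, 10⁴ probes). Every downstream stage runs end to end
on generated data with known ground truth.

## Quality control

Probe exclusions, in order: (1) assayed-SNP probes; (2) bead count < 3 in
≥ 5 % of samples (inclusive at the boundary — exclusionary rules default
inclusive); (3) detection p > 0.05 in > 1 % of samples (strictly greater,
as the rule is phrased); (4) SNP-overlapping or cross-hybridizing probes.
Sample exclusions: missing rate > 0.01; predicted sex (2-means split of
mean chrX beta; X inactivation raises mean chrX methylation in females)
disagreeing with reported sex; outliers on the first two classical-MDS
coordinates of pairwise Euclidean beta distance, flagged beyond 5 median
absolute deviations from the centroid (a conservative rule that excludes
nobody on clean data); samples from flagged distinct batches. Both filters
are idempotent: re-running on filtered data removes nothing.

## Normalization (dasen-style)

1. Per sample, Type I M and U intensities are shifted so their 5th
   percentile matches the Type II 5th percentile (a percentile-matching
   approximation to the original method's distribution-offset fit, which is
   under-specified in the literature; negative intensities are clipped at
   zero and counted).
2. Between-sample quantile normalization of M and U separately within each
   design type: each sample's sorted values are replaced by the
   across-sample mean of order statistics, ties resolved by average rank
   with linear interpolation.
3. β = M/(M+U+100), the standard Infinium offset.

A consequence worth knowing: between-sample quantile normalization
constrains every sample's value multiset to be identical, so a coherent
shift of a *large* block of probes in one sample is partially redistributed
across all other probes of that sample. On a real 850k array a 2,000-probe
module is 0.25 % of the probes and the leak is negligible; on a 10⁴-probe
simulation a module occupying several percent of the array leaks a visible
global component that surrogate-variable analysis can then absorb. The
analysis scripts therefore plant modules at ≈1 % of the array; this is a
genuine scale interaction, not an implementation artifact.

## EWAS with surrogate variables

Covariate design: intercept; case status; age; sex; study-area dummies;
fasting ≥ 8 h; education dummies; marital status; smoking (cigarette
equivalents/day); alcohol (g/day); physical activity (MET-h/day); diet
score (0–6); BMI. Zero-variance dummies are dropped with a warning;
genuine collinearity is an error naming the offending columns.

**Number of SVs.** Probes are residualized on the full design and
standardized; eigenvalues of the sample-space correlation structure are
compared with the Marchenko–Pastur upper edge (1+√γ)². Residualizing on p
covariates compresses the residual variance into n−p dimensions, which
inflates the whole spectrum; the spectrum is rescaled by (n−p)/(n−1) and γ
uses the effective dimension (n−p)/m. Without this correction pure-noise
data yields ~15 spurious factors at 5,000 × 200; with it, zero.

**SV estimation.** Iteratively reweighted SVD. Initial SVs are the top
right singular vectors of the full-model residual (case effect removed, so
initialization cannot chase the outcome). Each iteration computes, per
probe, an F-test p-value for association with the current SVs given the
null design, and one for association with case status given SVs; both are
converted to posterior probabilities of being non-null via a beta-uniform
mixture f(p) = π₀ + (1−π₀)·a·p^(a−1) fitted by maximum likelihood (a
smooth local-FDR estimate — binned estimates make the weights oscillate
and the iteration never settles). The probe weight is
P(latent) · (1 − P(case-associated)), and the SVs are refreshed as the top
right singular vectors of the weighted *null-model* residual (the
null-model residual retains latent structure that is correlated with case
status, which is exactly the confounding the SVs must capture). The loop
stops when the largest weight change falls below 10⁻³ (typically < 15
iterations) or at 50 iterations with a non-convergence flag. SVs are
standardized to unit variance and sign-fixed by positive correlation with
their highest-loading probe.

**Association.** Per probe, OLS of β on [design | SVs]; the reported
effect is the case coefficient (case-minus-control difference in
normalized beta), p from a two-sided t test with residual degrees of
freedom, floored at 10⁻³⁰⁰. Benjamini–Hochberg adjustment is step-up with
an optional family size m larger than the vector (used for module-specific
FDR against a stated family). Genomic inflation is
λ = median(χ²₁)/0.4549; Q-Q plotting positions use (i−½)/n. Per-SD odds
ratios come from unconditional logistic regression of case status on the
probe standardized by its own SD plus covariates and SVs, with Wald 95 %
CIs; non-convergence or separation yields a flagged record. The matched
design is analysed unconditionally with the matching factors as
covariates, mirroring the source design; within-pair conditional logistic
(logistic regression on within-pair differences without intercept) is used
as the recovery oracle in tests.

## Co-methylation network

Top-K probes by association p (ties broken by probe id) feed an unsigned
weighted network: adjacency a_ij = |cor(x_i,x_j)|^power with the smallest
power whose scale-free fit R² ≥ 0.8 *and* whose mean connectivity stays
≥ 1 (near-empty networks at high powers can look scale-free; fallback 6
with a warning). Topological overlap
t_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij); average-linkage
clustering of 1−t; fixed-height tree cut at 0.99 of the maximum merge
height, components ≥ 30 probes become modules (the "tree" variant of
dynamic tree cut — fully specifiable, unlike the hybrid variant); probes
above `block_size` are pre-partitioned by k-means (memory bound); modules
whose eigengenes have correlation dissimilarity < 0.25 merge iteratively.
Modules take the conventional colour names in decreasing size order;
unassigned probes are grey.

The module eigengene is the first right singular vector of the
probe-standardized module matrix, oriented to correlate positively with
the mean standardized profile. Module–trait association uses a rank-based
inverse normal transform of the eigengene, (rank−3/8)/(n+¼) → Φ⁻¹,
regressed on case status + covariates + SVs; a module is called at
Bonferroni p < 0.05/n_modules, and CpGs within a called module at
module-specific FDR < 0.01 (BH with family = module size).

Sample outliers before network construction: average-linkage clustering on
Euclidean distance, cut at mean + 3 sd of merge heights, clusters of < 3
samples excluded.

**Permutation guard.** Selecting the top K probes on the observed outcome
could manufacture case-associated modules. The guard shuffles case labels
within area × sex strata (respecting matched-design exchangeability),
re-runs the EWAS, re-selects top K, rebuilds modules, and records the
minimum module p; the empirical p is (1+#{perm ≤ obs})/(B+1), B = 100 by
default (reduced in tests).

## Risk-factor association and mediation

These models adjust for batch dummies instead of SVs: when methylation (or
a trait) is the model *outcome*, SVs estimated from the methylation matrix
are no longer valid covariates.

Lifestyle → CpG: one linear model per CpG with all five lifestyle factors
jointly plus demographics and batch; p < 0.05 screens a (CpG, factor) pair
into mediation. CpG → trait: methylation quartiles (sample quartiles, ties
to the lower quartile; ≥ 25 % ties is an error), trait regressed on
quartile indicators + covariates + batch, trend p from the quartile index
1–4 entered continuously. SBP/DBP are pre-adjusted +15/+10 mmHg for
participants on BP medication; glucose models additionally adjust diabetes
treatment.

Mediation uses the standard parametric pair: a linear mediator model
M = β₀ + β₁A + β₂ᵀC + ε(σ²) and a logistic outcome model with
exposure–mediator interaction, logit P(Y=1) = θ₀ + θ₁A + θ₂M + θ₃AM +
θ₄ᵀC. Rare-outcome closed forms on the log-odds scale for contrast
(a, a*), conditioning on covariate means c:

    log OR_NIE = (θ₂β₁ + θ₃β₁a)(a − a*)
    log OR_NDE = (θ₁ + θ₃(β₀ + β₁a* + β₂ᵀc + θ₂σ²))(a − a*)
                 + ½θ₃²σ²(a² − a*²)
    OR_TE = OR_NDE · OR_NIE       (an identity of the estimator)
    proportion mediated = log OR_NIE / log OR_TE

The proportion may be negative (opposing paths) or exceed one and is never
clipped; |log OR_TE| < 10⁻⁸ reports it as undefined. Standard errors by
the delta method over the stacked (β, θ) covariance assuming independence
of the two fits, treating σ² as fixed; a matched-pair bootstrap (pairs
resampled jointly) is available as an alternative for the proportion's SE.
Default contrast for continuous exposures: mean vs mean + 1 SD (per-SD for
CpG exposures). The mediator model is fitted on the full case-control
sample by default, mirroring the source analysis; a controls-only option
exists because the rare-outcome assumption is strained at 50 % case
prevalence. The closed forms carry an O(prevalence) approximation error:
against a Monte-Carlo counterfactual oracle the log-effect error is ≈0.01
at baseline log-odds −5 and ≈0.001 at −7, provided θ₂σ stays moderate
(≲1); with an implausibly strong mediator effect the rare-outcome
approximation degrades sharply.

## Synthetic-data generator

All effects are planted additively on logit(β) and squashed back, keeping
β ∈ [0,1] ("M-value-like" planting). Probe baselines draw from a bimodal
logit mixture (45 % low-methylated around logit⁻¹(−2.5), 45 % high, 10 %
intermediate). Latent factors (batch/cell composition) have sparse
Gaussian loadings and factor scores optionally correlated with case
status; planted modules are probe blocks sharing a module driver with
loading chosen so the within-module beta correlation hits the configured
target (module probes get mid-range baselines so the logistic squash stays
near-linear); causal probes shift by case status. Case status is assigned
within each matched pair from the two members' log odds (conditional-
logistic assignment), so exactly one case per pair holds while configured
log-odds remain recoverable by conditional logistic regression.

The two designated mediation probes are generated directly on the beta
scale so the analytic mediation truth (the closed forms above, evaluated
at the generating coefficients) is exact for the linear mediator model.
Their values are shared between the phenotype and methylation generators
through deterministic substreams of the master seed. Intensities are
M = βT, U = (1−β)T with a per-sample, per-design-type lognormal scale T
(Type I 25 % brighter), offset reconstruction error ≤ 100/(T+100).
Detection p-values are ~0 except planted Bernoulli failures drawn
U(0.05, 1); bead counts are 3 + Poisson(14) with planted low-bead cells;
chrX probes carry a +1.5 logit female shift used by the sex check.

What the generator does *not* emulate: genome-wide LD/co-methylation maps
(modules are disjoint blocks), realistic cell-type reference profiles
(latent factors are Gaussian), probe-specific chemistry biases beyond the
Type I/II scale difference, and spatial/array-position effects. Passing
tests therefore certify the statistical machinery under the generating
model, not performance on real arrays.

## Problem sizes and defaults

Defaults were chosen once as the desk-scale analogue of the study
conditions: 250 pairs (500 samples), 10⁴ probes, 3 latent factors, probe
noise sd 0.35 logits, total intensity 10⁴. Calibration runs use 10,000
probes × 500 samples; module recovery plants five modules of 100–300
probes (within-correlation 0.7) among 2,000 noise probes; mediation
recovery uses 200 replicates of n = 1,000 with true proportion 0.30; the
permutation guard runs at K = 500 of 2,000 probes with B = 50. The full
test suite completes in ≈1 minute on one CPU; the acceptance script in
≈30 s.

## Known limitations

- The dasen background step is a 5th-percentile match, not the original
  distribution-offset fit; systematic offsets between chemistries are
  equalized only at that quantile.
- The SV count estimator counts *all* reproducible latent structure —
  including genuine case-linked co-methylation drivers when they are
  large enough to cross the random-matrix edge; combined with the
  quantile-normalization leak above, SV adjustment can absorb a
  case-linked module on small arrays (see the Normalization section).
- Unconditional logistic analysis of the matched design is faithful to the
  source but not fully efficient; conditional logistic is available in
  tests as an oracle, not as a pipeline default.
- Rare-outcome mediation formulas are applied to a 50 % case-prevalence
  sample by design fidelity; the proportion mediated is robust to the
  implied attenuation (it cancels in the ratio) but the absolute ORs are
  conservative.
- Quantile normalization attenuates absolute per-probe effect sizes; the
  mediator coefficient of a planted pathway measured on normalized beta is
  systematically slightly smaller than the generating value.
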