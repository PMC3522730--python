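# Methods

This note documents the statistical models, numerical choices, and known
limitations behind `pathassoc`, in the spirit of a methods appendix.

## Study design being modelled

The package targets a frequency-matched case-control candidate-pathway
design: ~494 cases of advanced prostate cancer and ~536 controls from two
self-reported ethnic groups (~19% African American, ~81% Caucasian),
genotyped at 320 tag SNPs in 46 innate-immunity/inflammation genes grouped
into 6 biological sub-pathways, plus 39 ancestry-informative markers
(AIMs). The packaged catalog (`pathassoc.catalog`) reproduces the real
panel's gene symbols, sub-pathway membership, chromosomes, and per-gene
SNP counts; individual SNP identifiers are synthetic placeholders because
no per-SNP manifest is distributed.

## Quality control

A SNP is excluded when any of: call rate < 0.90; Hardy–Weinberg 1-df
chi-square p < 0.01 *in both* ethnic groups; MAF < 0.01 *in both* groups.
Samples with call rate < 0.90 are excluded. All thresholds are strict
inequalities, as printed in the protocol the filters mirror. Two
deliberately fixed conventions where the source protocol is silent:

* **Order** — sample filter first, SNP filters computed on retained
  samples (one pass; re-application is a no-op, verified by test).
* **HWE test** — the 1-df Pearson chi-square against expected proportions
  (p², 2pq, q²), matching the era's practice; an exact test would be a
  drop-in alternative but is not implemented.
* **Minor allele** — defined on the full sample, frequency ties broken
  lexicographically by allele symbol.

## Ancestry

AIM genotypes are standardized per SNP in the EIGENSTRAT convention
(mean-impute missing, center at 2p̂, scale by √(2p̂(1−p̂))) and
decomposed by SVD. Component signs are fixed so each component's
largest-magnitude loading is positive (reproducibility across LAPACK
backends; association p-values are invariant to the sign, verified by
test). Only PC1 enters downstream models as the genetic-ancestry
covariate; k is configurable. PCA is computed on AIMs only, never on the
candidate SNPs.

## Kernel-machine set test

Null model: covariate-only logistic regression (intercept, age,
institution indicator contrasts, ancestry PC1), fit by Newton/IRLS to
gradient tolerance 1e-10, max 100 iterations (statsmodels backend).
Perfect separation and non-convergence raise explicit errors. In
ethnicity-stratified runs the ancestry covariate is retained (it varies
within strata); covariate columns that are constant within a stratum
(e.g. an institution indicator at a single-site stratum) are dropped with
a warning.

Statistic: `Q = rᵀGGᵀr` with `r = y − ŷ` and G the mean-imputed
minor-allele-count matrix of the set — the **unweighted** linear kernel.
No MAF weighting is applied: with identity weights the kernel test is the
variance-component score test of the corresponding multivariate logistic
model, which is the construction being mirrored; weighted and non-linear
kernels are out of scope.

Null distribution: `Σ λⱼ χ²₁` with λ the eigenvalues of `P₀½KP₀½`,
computed on the p×p matrix `GᵀP₀G` (identical non-zero spectrum, cheaper
for p ≪ n). Eigenvalues below 1e-10 × λmax are discarded as numerical
noise. Genes with a single SNP are reported "not tested" at set level —
the rank-1 kernel test is identical to the per-SNP 1-df score test (an
identity verified to 1e-8 in the tests), so the per-SNP analysis covers
them.

### Davies p-values

`P(Q > q)` is computed by Gil-Pelaez/Imhof inversion of the
characteristic function,

    P(Q > q) = 1/2 + (1/π) ∫₀^∞ sin θ(u) / (u ρ(u)) du,

split at a point A chosen so the head contains few oscillations: the head
integral uses adaptive quadrature; for the tail, the exact identity
θ(u) = kπ/4 − ½Σ arctan(1/(λⱼu)) − qu/2 rewrites the integrand as
smooth-times-sin/cos(qu/2), integrated by QUADPACK's Fourier-weighted
rule. Requested absolute accuracy is 1e-6; the achieved accuracy is
~1e-12 against an independent arbitrary-precision oracle. If the
quadrature error estimate exceeds 1e-6 or the inverted value leaves
[0, 1], the Liu–Tang–Zhang moment-matching approximation is used and the
result is labelled `method="liu"` — never a silent fallback. Liu's
approximation agrees with Davies to ~1e-3 typically and ~2e-2 worst-case
in the distribution body, which is why it is only a fallback.

For permutation work, where thousands of statistics share one spectrum, a
vectorised evaluator computes the same integral on a common midpoint grid
(truncation point from an integration-by-parts tail bound anchored at a
few percent of the mixture mean; ≥12 grid points per sin cycle), with
monotone PCHIP interpolation across sqrt-spaced q-nodes; accuracy ~1e-5,
with statistics beyond the grid's oscillation resolution deferred to the
scalar routine.

## Per-SNP models

Codominant (heterozygote and rare-homozygote indicators vs
common-homozygote reference, matching the conventional genotype-table row
order) and log-additive (0/1/2 trend) codings; unconditional multivariate
logistic regression with the same covariates; Wald 95% CIs
(exp(β ± 1.96·SE)) and two-sided Wald p-values. A contrast with any empty
genotype-by-status margin cell is flagged *undefined* and rendered with no
numbers — zero-cell detection, not convergence heuristics, so unstable
huge odds ratios are never reported. Missingness is handled per-SNP
complete-case (per-SNP n varies). With no covariates the fitted ORs equal
contingency-table cross-product ratios to 1e-6 (tested).

## Permutation min-P FWER

For each grouping level (pathway / sub-pathway / gene / SNP), B
permutations of the case/control labels are drawn — by default within
strata defined by ethnicity × institution, preserving the
frequency-matched design (a raw shuffle is available; strata of size 1
keep their label and are logged). Every test of the level is recomputed
on each permuted data set; the adjusted p-value of a test with observed
p₀ is

    p_adj = (1 + #{b : minP_b ≤ p₀}) / (B + 1),

never zero and monotone in p₀. Because the Monte-Carlo estimate can
undercut p₀ at small B, adjusted values are clipped from below at the
observed p-value (an adjusted p-value cannot be smaller than the
unadjusted one). Kernel-level recomputation refits the covariate-only
null model on every permuted label vector. SNP-level recomputation uses
the 1-df log-additive *score* test (vectorisable across 320 SNPs),
the permutation-friendly analogue of the reported Wald trend test — at
B = 1000 refitting 320 Wald models per permutation would be prohibitive,
and score and Wald tests are asymptotically equivalent. Default B = 1000;
deterministic given (seed, B).

## Power

The detectable-odds-ratio tool inverts the analytic power of the
two-sided 1-df allelic test comparing allele frequencies between 2·n_case
and 2·n_control alleles: control frequency p₀ = MAF, case frequency from
odds multiplication, power = Φ((|p₁−p₀| − z_{α/2}·SE₀)/SE₁) with pooled
SE under the null and the unpooled SE under the alternative, bisection to
the target power. The default α is the Bonferroni level 0.05/320 for a
320-test panel: it is the level at which the inverted bounds reproduce
the design's published detectable-OR range (≈1.5 at MAF 0.5, ≈2.19 at
MAF 0.05, protective reciprocals ≈0.67/0.46), whereas a nominal α = 0.05
yields far smaller bounds; the level is configurable and this inference
is deliberate, not a claim about the original computation. The protective
bound is the reciprocal of the risk bound by construction. The analytic
power matches simulation within Monte-Carlo error (tested).

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
not sequence-level realism:

* **Population structure** — two populations with Balding–Nichols
  Beta-distributed per-population frequencies (default Fst 0.10 for
  candidate SNPs); AIMs get a fixed between-population frequency gap
  (default 0.40), which makes PC1 separate the populations as in real
  AIM panels.
* **LD** — within each gene, haplotypes follow a latent Gaussian AR(1)
  copula (default ρ 0.5) thresholded at the frequency quantile; two
  haplotypes sum to a genotype, so marginals are in Hardy–Weinberg
  proportions and pairwise r² decays with distance. There is no
  recombination map, no haplotype copying, and no X chromosome.
* **Phenotype** — disease follows a logistic model with configurable
  per-allele log-ORs (defaults emulate small protective effects,
  OR ≈ 0.73–0.77) and covariate effects; the intercept is calibrated by
  bisection to the target case fraction; ages are truncated-normal
  (65.9 ± 8.4, bounds 40–90); three institutions (multinomial
  0.5/0.3/0.2).
* **Matching** — exactly n_cases cases are drawn, and controls are
  frequency-matched to the cases' 5-year-age-bin × ethnicity
  distribution; when a cell lacks candidate controls the generator
  borrows from adjacent age bins within the same ethnicity before
  failing.

Because genotypes are generated from the model the tests assume,
calibration results (uniform null p-values, nominal type-I and
family-wise error) demonstrate internal statistical validity, not
robustness to real-data pathologies such as differential genotyping
error, cryptic relatedness, or fine-scale admixture.

The QC fixture (`simulate_qc_fixture`) builds 330 SNPs of which 10
violate exactly one filter each (4 low call rate, 3 Hardy–Weinberg
failures in both groups, 3 rare in both groups); the clean SNPs are
placed in exact Hardy–Weinberg proportions so the fixture's expected
outcome is deterministic for any seed.

## Calibration problem sizes

The statistical acceptance checks use sizes chosen to give informative
Monte-Carlo resolution on a single CPU: type-I error over 2000 null
replicates (n = 500, 10-SNP set); family-wise error over 500 replicates
of the full 46-gene family (n = 300, B = 200, covariate-free null so
per-set spectra are reusable across permutations); effect recovery over
500 replicates of the 494/536 design. The 95% binomial interval at these
replicate counts is the acceptance band.

## Known limitations

* The Davies mixture is the *asymptotic* null; at n ≈ 200 its tail
  probabilities differ from the exact permutation law by up to ~1%
  (smaller without covariates), which is visible when comparing against
  very large permutation counts.
* No imputation, phasing, multi-allelic variants, X-dosage handling,
  haplotype analysis, exact logistic regression, or Firth correction
  (the latter would be the natural extension for sparse strata).
* Stratified analyses reuse the full-sample ancestry PC1 rather than
  re-estimating ancestry within stratum; the choice is deliberate and
  fixed.
* The SNP-level FWER family uses score-test p-values while the reported
  per-SNP tables are Wald-based (asymptotically equivalent; documented
  above).
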