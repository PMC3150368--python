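# Methods

This note documents the statistical procedures implemented in `popstruct`,
the defaults chosen where a genuine design decision was required, and what
the synthetic-data tests do and do not demonstrate about real data.

## Synthetic cohort model

`simdata` generates multi-study, spatially structured genotype sets under
the Balding–Nichols model: each SNP has an ancestral frequency
p ~ Uniform(maf_lo, maf_hi) (default 0.05–0.5), and subpopulation k draws
its frequency from Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), so
E[p_k] = p and Var[p_k] = F_k·p(1−p); F_k = 0 uses p exactly. Genotypes
are Binomial(2, p_k). Defaults describe six county-like subpopulations on
a south-to-north transect (latitude 55°–65°), with divergence growing
linearly from F = 0.0005 to F = 0.002 — the magnitude of differentiation
seen between well-separated regions within a single Northern-European
country — sampled by three genotyping studies. Study labels are assigned
round-robin within subpopulation so study and geography are unconfounded
unless `confound_study_with_subpop` is set.

SNP positions lie on uniformly spaced maps (default 50 kb on two synthetic
chromosomes) because the ROH filters are bp-denominated. Optional planted
artifacts — duplicate/parent-offspring/full-sib pairs, samples with
allele-level ancestry from a divergent source population (mixture weight
α), per-study missingness, strand flips (complementary-base relabeling plus
2−g recoding in one study), and autozygous runs (both haplotypes copied
from one population draw) — are recorded in a `SimTruth` object for
recovery tests. All randomness derives from a single seed; each stage uses
an independent child stream (fixed spawn keys), so injections are
order-independent and output is bit-reproducible.

The generator makes no attempt at coalescent realism: no recombination or
LD beyond what planted duplicated columns induce, no phased haplotypes, no
mutation model, no sex chromosomes. Tests passing on this substrate show
that the estimators recover the quantities the generator controls
(divergence, kinship, autozygosity, batch artifacts) at the stated
tolerances — not that the pipeline is robust to LD structure, genotyping
intensity artifacts, or call-rate patterns of real arrays.

## Merging and quality control

Datasets are merged on the SNP intersection restricted to a reference
dataset (by default the largest study). Allele pairs are reconciled
allowing swaps and strand complements; strand-ambiguous A/T and C/G SNPs
cannot be complement-normalized and are compared literally. Irreconcilable
SNPs are dropped and reported separately from the filter accounting.

SNP filters, each evaluated on the merged pre-QC matrix so removal can be
attributed both totally and "solely to that reason":

- call rate < 0.95 in **any** study;
- minor allele frequency < 0.01 in all studies combined;
- Hardy–Weinberg exact test p < 10⁻⁶ in all studies combined;
- 1-vs-rest allelic chi-square p < 10⁻⁶ in any study-vs-rest comparison
  (catches undetected strand flips and platform artifacts).

The HWE test is the exact conditional test (probabilities of all
heterozygote counts compatible with the observed allele counts, summing
those not exceeding the observed configuration's), not the asymptotic
chi-square — the exact test is stable at the 10⁻⁶ tail where the decision
is made. The 1-vs-rest comparison uses the allelic (allele-count) 1-df
chi-square, consistent with the power-simulation statistic. A strand flip
is only statistically detectable when the allele frequency is asymmetric;
a flip at MAF ≈ 0.5 is invisible to any frequency-based test.

Sample QC runs after SNP QC: method-of-moments IBD estimation from
IBS0/IBS1/IBS2 counts given combined-sample allele frequencies (state
probabilities truncated to [0,1] and renormalized;
π̂ = P(IBD=2) + P(IBD=1)/2), greedy removal while any pair exceeds
π̂ > 0.20 (dropping the member with higher missingness; tie → higher
index — the tie-break is a documented convention, any rule satisfying the
"no remaining pair above threshold" postcondition is defensible), then
removal of samples with missingness strictly above 2% computed on the
post-QC marker set. Pairs sharing fewer than 100 informative SNPs are
flagged unreliable.

## LD pruning

Windowed pairwise-r² pruning: a 200-SNP window advancing 25 SNPs within
each chromosome; within a window the highest-r² pair above 0.2 is resolved
repeatedly until none remains; the whole scan runs twice. r² is the squared
Pearson correlation of dosages over pairwise-complete samples, with
zero-variance columns defined as r² = 0. The pair-removal rule — higher
missingness, then lower MAF, then larger position — is fixed purely for
reproducibility; pruning tools leave this to internals. A brute-force
single-window oracle (`prune_bruteforce`) verifies the windowed
implementation on small instances.

## PCA, projection, and ancestry exclusion

Genotypes are Patterson-normalized: column j is centered by its mean
dosage μ_j and scaled by s_j = sqrt(p̂_j(1−p̂_j)) with
p̂_j = (1 + Σg)/(2 + 2n) over non-missing entries (the +1/+2 pseudo-count
keeps the scale finite for near-monomorphic columns); missing entries
become 0 after centering. The top-K components come from the SVD of the
normalized matrix; eigenvalues are singular values squared over (n−1), and
each weight vector is oriented so its largest-magnitude loading is
positive, making signs reproducible across runs. The stored (μ, s, weights)
triple projects held-out samples onto the training axes; a training sample
reprojects onto its own score to numerical precision, and an all-missing
sample lands at the origin.

Ancestry exclusion is a configurable half-plane in the (PC1, PC2) plane
(unit normal + offset; strict inequality, so boundary samples are kept) —
the cutoff is supplied by the analyst, never inferred. Residual outliers
are removed by the k-th-nearest-neighbor rule: for k = 1…5, each sample's
distance to its k-th neighbor is z-scored and samples beyond 4 SD are
removed, accumulating over k (the k ≥ 2 sweep catches pairs of outliers
that are close to each other). Distances are computed in the
normalized-genotype space by default (PC space is configurable). Note the
false-removal rate of a plain z-score cut depends on the dimensionality:
k-NN distances are right-skewed in low dimension but close to Gaussian in
the high-dimensional genotype space, where the expected number of null
removals is n·k_max·P(Z>4) ≪ 1 per 500 samples.

Geography models: OLS of a component on latitude, on longitude, and the
ΔR² of adding longitude to the latitude model; Nagelkerke pseudo-R²
((1−(L0/L1)^(2/n))/(1−L0^(2/n))) for binary ancestry labels, with perfect
separation reported as a failure rather than a number; variance-share
(fraction of a component's total sum of squares contributed by a sample
subset); and seeded uniform coordinate jitter for de-identified map
tables.

## F_st and genomic inflation

The Hudson estimator was chosen because it has no systematic dependence on
sample size or on the ratio of group sizes, and because the λ translation
treats F_st as a population quantity; the per-SNP numerator subtracts the
finite-sample variance of each frequency estimate (allele-count
denominators n−1), and SNPs are combined as a ratio of sums, never an
average of per-SNP ratios. Monomorphic-in-the-pair SNPs and groups below a
configurable minimum size (default matches excluding a 12-sample group
while keeping ≥65-sample groups) are excluded. A block-jackknife over SNP
blocks supplies a standard error. Expected inflation of a fully stratified
study is λ = 1 + n_total·F_st, with negative estimates floored at zero for
the translation, clustering, and MDS.

The F_st matrix is summarized by complete-linkage agglomerative clustering
(distances floored at 0; deterministic tie handling via the canonical
condensed ordering) with Newick export, and by classical (Torgerson) MDS —
double-center −D²/2, eigendecompose, truncate negative eigenvalues — with
a raw-stress diagnostic.

## Runs of homozygosity

A window of 20 SNPs slides one SNP at a time along each chromosome; a
window is homozygous if it contains at most one heterozygous call. Missing
genotypes count as neither heterozygous nor homozygous (window counts are
unaffected), matching common tooling. A SNP is a candidate when at least
10% (≥, "at least") of the windows covering it are homozygous; maximal
candidate runs whose boundaries are the first/last candidate SNP positions
become segments if ≥1 Mb, ≥50 SNPs, and ≤5% heterozygous calls. The
scanner is verified against a brute-force oracle that enumerates every
window and overlap fraction explicitly. Segment calls are invariant to
allele orientation (heterozygosity is). Chromosomes shorter than one
window yield no calls. BED-style output converts the internal 1-based
inclusive coordinates to 0-based half-open.

The per-sample inbreeding coefficient is the excess-homozygosity
method-of-moments estimate F = (O_hom − E_hom)/(N − E_hom) with
E_hom = Σ_j (1 − 2p_j(1−p_j)·2n/(2n−1)) over the sample's usable SNPs.
Segment counts are modeled with a log-link Poisson regression on latitude
(or on group against a configurable baseline), always adjusting for source
study as a categorical covariate; group-coefficient p-values are
Bonferroni-adjusted across groups (configurable). ROH analysis should be
run on directly genotyped markers — imputation systematically biases
homozygosity — which is why the pipeline runs the scan on the (pruned)
genotype data it was given, and why per-dataset provenance belongs in the
metadata.

## Power under stratification

Sampling is at the allele level: case allele counts ~ Binomial(2·n_cases,
p_case) with p_case = OR·p/(1−p+OR·p), control counts ~ Binomial(2·n_controls,
p). This assumes Hardy–Weinberg equilibrium and matches the 1-df allelic
chi-square computed on the resulting 2×2 table. Genomic inflation is
applied as statistic deflation — each chi-square is divided by λ before
comparison with the χ²(1) critical value at α = 5×10⁻⁸ — which is
algebraically identical to inflating the critical value by λ (tested as an
identity). Power is the rejection fraction over 10,000 replicates (default)
with an exact Clopper–Pearson interval. Degenerate tables count as
non-rejections.

Two reference computations accompany the simulator: the noncentral
chi-square closed form with noncentrality
(p1−p2)²/(p̄(1−p̄)(1/(2n1)+1/(2n2))), and an exact enumeration of the joint
binomial count distribution. The closed form is a normal approximation and
can deviate from the exact law by ~2–3 percentage points at some MAF/OR
combinations; the tight simulation checks therefore use the exact
enumeration, with the closed form held to a looser band.

## Pipeline

Stages run in the order merge → SNP/sample QC → LD pruning → PCA →
ancestry-cutoff and k-NN exclusions (each skippable) → geography
regressions → F_st/λ with clustering and MDS → ROH and count models →
power grid. Stages needing metadata (geography, F_st, study-adjusted
models) are skipped with an explicit notice when it is absent; earlier
stages still run. A manifest records the seed, the config, and a SHA-256
hash of every emitted file; stage outputs are pure functions of (inputs,
config, seed), so reruns are hash-identical.

## Problem sizes used in the test suite

The suite exercises the estimators at the sizes where their tolerances are
meaningful while staying lightweight: 10⁵ SNPs × 200 samples for F_st
recovery, 10⁴ SNPs for kinship means (50 pairs per class), 5,000
observations for Poisson coefficient recovery, 10,000 replicates for the
headline power scenarios, and ≤500-SNP fixtures for exact oracle
agreement. These were chosen as the smallest sizes at which the Monte-Carlo
error is comfortably below each assertion's tolerance.

## Known limitations

- The synthetic generator draws SNPs independently; LD-pruning behavior on
  realistic haplotype structure is validated only against the small-instance
  oracle, not against population LD patterns.
- π̂ estimation assumes the allele frequencies of a homogeneous sample;
  in strongly structured samples it inherits the usual method-of-moments
  biases (it is used here after merging, as a screen at threshold 0.20).
- The half-plane ancestry cutoff is two-dimensional by design; ancestry
  signals spread over more components require the projection tools plus an
  analyst-defined rule.
- `lambda_from_fst` is the expectation for a *fully* stratified design;
  partial overlap of case and control sampling regions yields smaller
  inflation.
- The power simulator models a single biallelic SNP under HWE with an
  allelic test; genotype-level tests, covariate adjustment, and
  logistic-regression variants are out of scope.
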