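# popstruct

Population-structure analysis of genome-wide SNP data for multi-study
control collections: cross-study merging and quality control, LD pruning,
PCA-based ancestry exclusion and projection, pairwise F_st with translation
to the expected genomic-control inflation λ, runs-of-homozygosity (ROH)
analysis, and simulation of case-control power loss under stratification.

It is aimed at statistical geneticists assembling GWAS control panels from
heterogeneous sources, where within-country structure (e.g. a north-south
allele-frequency gradient) can inflate association statistics or mask real
signals. Because real cohorts of this kind are rarely distributable, the
package ships a synthetic-data module that generates spatially structured
multi-study genotype sets with known ground truth — planted relatives,
admixed samples, batch artifacts, and autozygous segments — so every stage
of the pipeline is testable end to end.

## Core quantities

- **Pairwise F_st** between sample groups uses the Hudson estimator combined
  across SNPs as a ratio of averages:
  `F_st = Σ_j N_j / Σ_j D_j` with
  `N_j = (p̂1−p̂2)² − p̂1(1−p̂1)/(n1−1) − p̂2(1−p̂2)/(n2−1)` and
  `D_j = p̂1(1−p̂2) + p̂2(1−p̂1)`, where n is the sampled allele count.
- **Genomic inflation** of a fully stratified case-control study of
  `n_total` samples is `E(λ_GC) = 1 + n_total · F_st`.
- **PCA** operates on Patterson-normalized dosages (centered, scaled by
  `sqrt(p̂(1−p̂))`); the stored per-SNP weights and normalization constants
  project held-out samples onto the training axes.
- **ROH** are called with a 20-SNP sliding window (≤1 heterozygote per
  homozygous window, SNP in a run when ≥10% of covering windows are
  homozygous), filtered to ≥1 Mb, ≥50 SNPs, ≤5% heterozygotes; per-sample
  segment counts are modeled with a study-adjusted Poisson regression.
- **Power under stratification**: per replicate, case/control allele counts
  are drawn binomially, the 1-df allelic chi-square is divided by λ, and
  rejection is judged at the genome-wide threshold 5×10⁻⁸.

## Worked example

Power of a 500-case / 500-control study for a risk allele at control MAF
0.16 or 0.10 with allelic odds ratio 2, with and without a genomic
inflation of λ = 2:

```sh
popstruct power --maf 0.16,0.10 --or 2 --lambda 1,2 --reps 10000 --seed 7 \
    --out power.tsv
```

```
 maf  odds_ratio  lambda_gc  power   ci_low  ci_high  n_replicates  n_rejections  power_analytic
0.16         2.0        1.0 0.8028 0.794864 0.810559         10000          8028        0.795067
0.16         2.0        2.0 0.0735 0.068460 0.078790         10000           735        0.075804
0.10         2.0        1.0 0.4295 0.419770 0.439271         10000          4295        0.423477
0.10         2.0        2.0 0.0058 0.004407 0.007491         10000            58        0.007123
```

A comfortably powered scenario (80% at MAF 0.16) collapses to under 10%
when the study is fully stratified at λ = 2 and genomic control is applied;
at MAF 0.10 power falls from ~40% to almost nothing. `power_analytic` is
the noncentral chi-square closed form shown for comparison; the exact
binomial enumeration is available as `popstruct.stratsim.exact_power`.

The full pipeline runs from a YAML config over PLINK 1 filesets
(`popstruct run --config config.yaml`), or stage by stage
(`popstruct simulate | qc | prune | pca | fst | roh | power`), writing
tab-separated tables, a QC report, a Newick dendrogram of the F_st matrix,
and a manifest with per-file content hashes (reruns with the same seed are
hash-identical).

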