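# Methods

## Model and assumptions

The discovery test operates entirely in Z-score space. For each SNP the
per-trait univariate GWAS Z-scores **z** = (β̂₁/SE₁, …, β̂ₖ/SEₖ) are, under
no association, jointly multivariate normal with mean zero and covariance
equal to the matrix of phenotypic correlations V₀ among the traits
(traits measured on overlapping samples share residual noise; genotype
enters each univariate regression identically). The joint statistic is the
quadratic form

    T² = zᵀ V₀⁻¹ z  ~  χ²(k)  under H₀,

with k the number of traits in the group. Under association the statistic
is non-central with non-centrality δᵀV₀⁻¹δ, where δ is the vector of
per-trait expected Z — which is why evidence spread over several correlated
traits (pleiotropy) can reach significance jointly while no single trait
does.

Assumptions worth stating: (i) the per-trait scans come from one cohort (or
fully overlapping cohorts), so V₀ captures the Z cross-correlation; (ii)
effect sizes are small enough that the univariate Wald Z is approximately
normal; (iii) the same allele frame is used across traits. Allele
harmonization across data sources is handled upstream (rsid join, (chrom,
pos) consistency check, sign flip on reference/effect swap; A/T and C/G
pairs are kept within a single cohort but excluded from cross-cohort
direction checks because their strand cannot be resolved from summary data).

## Estimating V₀

V₀ is the Pearson correlation of the Z columns across SNPs. By default all
SNPs contribute: genome-wide panels are overwhelmingly null, and the
handful of true signals moves the estimate negligibly at realistic panel
sizes (sampling error ≈ (1−r²)/√N_SNP). An optional `null_filter` drops
SNPs with max |Z| above a cap before estimating; note that truncation
attenuates correlations, so the filter is off by default and intended only
for panels with pervasive strong signal. The diagonal is forced to exactly
1, and the estimate is validated (symmetry, PSD up to −1e−10, |r| ≤ 1).

Per-group V₀ is re-estimated on the group's columns; for Pearson
correlation this is identical to taking the submatrix of the full-trait
estimate (a test asserts the equivalence).

## Numerical choices

- **P-values in log space.** `chi2.logsf` carries the tail to ln p ≈ −705;
  beyond that an asymptotic expansion of the upper incomplete gamma
  function takes over, so log₁₀ p is finite for any finite T² (statistics
  in the hundreds are routine at strong loci). Text output clips the
  linear p at 1e−300 and always carries log₁₀ p alongside.
- **Ill-conditioned V₀** (condition number > 1e8) is a hard error naming
  the remedy; optional ridge shrinkage (1−ε)V₀+εI with ε = 0.01 sits
  behind an explicit flag because silent regularization changes p-values.
- **T² via Cholesky whitening**, vectorized over SNPs; a per-SNP solve is
  kept for scalar use and the two are asserted equal to 1e−10.
- **Inflation factor** λ = median(χ²_obs)/median(χ²(df)) uses the group's
  df for multivariate traits (a convention, logged with each λ; the
  alternative — mapping to 1 df — rescales λ but not its qualitative
  reading).
- **Clumping tie-break**: equal p resolved by (chromosome, position), so
  the greedy procedure is deterministic; an exhaustive enumeration oracle
  checks it on random instances.
- **Locus merging** runs to a fixed point over three symmetric predicates
  (window overlap, lead Z-profile r² ≥ cutoff, shared configured region),
  making it idempotent and input-order independent. Merging crosses trait
  groups: a region significant for several groups is one locus, labelled
  by the minimal-p group with all passing groups recorded.
- **Ward clustering** operates on 1 − |ρ| distances directly; scipy's
  linkage gives a deterministic merge order (lowest pair index on ties).
- **Spearman p** uses the t-approximation with m − 2 df (ample for a
  trait panel of a few dozen); a seeded permutation p is available for
  small panels.

## Defaults and their rationale

| parameter | default | why |
|---|---|---|
| locus window | ±500 kb | conventional clumping radius for livestock LD |
| merge regions | chr6 22–42 Mb, chr11 24.5–28 Mb, chr18 62–67 Mb | the three large LD blocks on Oar_v3.1 known to carry strong carcass signals; explicit config replaces by-eye merging of regional plots |
| LD-merge r² | 0.7 | the same cutoff used to call SNPs "in LD" with a lead for annotation |
| α | 0.05 | nominal level before Bonferroni over SNPs × groups |
| replication min n | > 20 strictly | an interval-trait enters the joint test only with a workable univariate sample |
| MAF / call-rate gates | > 1%, > 95% | standard pre-replication genotype QC |
| shrinkage ε | 0.01 | barely perturbs a well-conditioned V₀, tames a near-singular one |

## The synthetic-data generator

`simulate_study` emulates the data-generating process the analysis
assumes, at desk scale (defaults: 2,000 individuals, 50,000 SNPs, 18
standardized traits grouped 9/6/3): genotypes Binomial(2, MAF) independent
across SNPs, phenotypes Y = G·B + E with equicorrelated residuals
(default r = 0.5) and effects in trait-SD units, causal SNPs pleiotropic
within one trait group, and per-SNP per-trait OLS Z-scores. Two features
of real data are deliberately absent: **linkage disequilibrium** (SNPs are
independent; Z-profile LD logic is exercised with duplicated/shared causal
signals instead) and **population/family structure** (no relatedness, no
mixed models — the replication stage consumes externally produced
mixed-model GWAS tables rather than fitting them). Passing tests therefore
demonstrate correctness of the statistics and algorithms under the model's
own assumptions, not robustness to stratification or LD-induced clump
ambiguity on real genomes.

`simulate_null_z` draws Z rows i.i.d. MVN(0, V₀) — the exact null of the
summary-statistic test — and drives the calibration checks (100,000 SNPs
per group: type-I error at 0.05 within the binomial 3σ band, λ within 2%
of 1, KS agreement of T² with χ²(df)).

## The individual-level oracle

`manova_oracle` is a likelihood-ratio MANOVA computed from residual
cross-product determinants, LR = n·ln(det E₀/det E₁) ~ χ²(k) — no
standard errors, no V₀, hence computationally independent of the Z path
(and cross-checked against statsmodels' Wilks-Λ MANOVA in a test). The
equivalence check scores 200 SNPs in a cohort of 1,000 individuals while
estimating V₀, by the summary-statistic method itself, from a 5,000-SNP
null panel of the same cohort. That mirrors real practice, where V₀ comes
from the genome-wide panel (hundreds of thousands of SNPs), not from the
handful of SNPs under scrutiny; with V₀ estimated from only the 200 scored
SNPs its sampling noise (SE ≈ 0.05 per entry) dominates the comparison and
the two paths visibly diverge, which is a statement about 200-SNP
correlation estimates, not about the statistic. Under the genome-wide-panel
design the −log₁₀ p agreement is r > 0.999 with max discrepancy ≈ 0.1.

## Pipeline configuration (YAML)

```yaml
sumstats: sumstats.tsv          # required
columns:                        # required: explicit column mapping
  rsid: rsid
  chrom: chrom
  pos: pos
  ref_allele: ref_allele
  eff_allele: eff_allele
  z: {MMass_t0: z_MMass_t0, ...}   # or beta:/se: mappings per trait
trait_groups:                   # required
  MMass: [MMass_t0, ...]
output_dir: out                 # required
reference_map: chip_manifest.tsv   # optional: harmonization target
known_loci: known.tsv           # optional: name, chrom, start, end
n_samples: 10613                # enables variance-explained
alpha: 0.05
window_kb: 500
merge_regions: [{chrom: "6", start: 22000000, end: 42000000}, ...]
ld_merge_r2: 0.7
null_filter: null               # e.g. 2.0 to cap |Z| in V0 estimation
shrink_v0: false
cap_log10p: null                # e.g. 14 to omit extreme SNPs in Manhattan
locus_labels: {rs123: GENE}     # cosmetic node labels for the network
```

Unknown keys are rejected. Two runs with the same config and inputs
produce byte-identical TSVs (figures exempt).

## Problem sizes used in the checks

Null calibration uses 100,000 SNPs per group; the oracle comparison 1,000
individuals × 5,200 SNPs; V₀ recovery 20,000 SNPs; power 500 replicates of
a 2,000-individual cohort; clumping 200 random instances. These sizes put
Monte-Carlo error well inside each check's acceptance band while keeping
the whole suite in the tens of seconds.

## Known limitations

- Effect sizes are not returned by the joint test; it is a detection
  statistic. Per-trait directions come from the univariate Z.
- The variance-explained figure is a univariate, single-SNP quantity
  (χ²(1) quantile at the best univariate p over n); it ignores LD between
  member SNPs and multi-SNP haplotype effects.
- Novelty annotation depends entirely on the supplied known-loci table and
  its assembly; no liftover is performed.
- The replication stage assumes biallelic SNPs when aligning effect
  alleles across pools, and treats strand-ambiguous SNPs as indeterminate
  for direction consistency rather than guessing strand from frequency.
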