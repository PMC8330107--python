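# Methods

## Model and procedure

`domaindiff` treats a chromatin domain partition as fixed input and asks
whether the genes inside each domain change expression together between two
sample conditions. The statistical object is the per-domain gene set; all
coordinates are 0-based half-open internally (BED native; GFF3/GTF converted
on read).

**Gene-to-domain assignment.** Each gene is assigned to the domain
containing its transcription start site (TSS: `start` on the + strand,
`end − 1` on the −). When the TSS falls in a gap between domains but the
gene's 3′ end lies inside a domain, the gene is rescued into that domain.
A TSS exactly on a domain start belongs to that domain; one on the end
coordinate belongs to the next (half-open convention). Genes matching
neither rule are recorded as unassigned, not errors. Assignment is
deterministic and independent of input order.

**Pre-processing.** For count-scale input, genes need a value ≥ 5 in at
least 80% of samples; each sample is then scaled by its upper quartile of
nonzero values (×1000). Differential expression runs on log2(scaled + 1);
correlations run on quantile-normalized log values; expression classes for
the permutation nulls use the mean filtered expression per gene. Domains
are retained with between 3 genes and the dataset-specific 99th-percentile
gene count. The percentile uses the nearest-rank quantile: the cap is then
always an observed count, so the rule cannot drop the maximum of a small,
unexceptional count distribution, while a genuine 1-in-100 outlier still
falls above the 99th rank.

**Quantile normalization** is standard rank-mean: the reference is the
per-rank mean of column-sorted values, and a tie group receives the mean of
the reference values spanning its ranks. With ties, column distributions
therefore agree only up to tie-group averaging; exact pairwise equality of
sorted columns holds for tie-free (continuous) data.

**Moderated differential expression.** A two-group empirical-Bayes
moderated t: gene-wise residual variances s²_g (pooled, df = n₁ + n₂ − 2)
are shrunk toward a prior s₀² with d₀ degrees of freedom estimated by
moment-matching log s²_g against a scaled F distribution (digamma/trigamma
inversion; d₀ = ∞ when observed spread does not exceed chi-square sampling
noise, giving a fully pooled variance and normal tails). The statistic is
the mean log2 difference over the posterior standard deviation; p-values
use t with d₀ + df degrees of freedom. `prior_df=0` recovers the ordinary
pooled t (tested against an independent implementation). The fold-change
sign convention is condition 2 over condition 1, condition order taken from
first appearance in the sample annotation.

**FCC.** Genes with log2 fold-change exactly 0 carry no sign and are
excluded from their domain's score; an all-zero domain scores the
degenerate value 0. The domain keeps its membership — only the informative
subset enters the formula. FCC is scale-invariant, symmetric under a global
sign flip, permutation-invariant, and bounded in [−1, 1] (property-tested).

**Permutation null and AUC ratio.** Genes are split into 5 equal-sized
classes by mean expression (ties broken by gene id); each permutation
shuffles gene→domain-slot assignments within a class, preserving every
domain's class composition. Per permutation, FCC is recomputed for all
domains and the decreasing-rank cumulative sum taken; the null curve is the
pointwise 95th percentile over permutations. The AUC ratio is the
trapezoidal area of the observed curve over that of the null curve on the
unit-spaced rank grid. Defaults: 10,000 permutations (a 100,000-permutation
parity mode is a flag away); a single top-level seed feeds per-stage
`numpy` Generator streams.

Because the denominator is a 95th-percentile *envelope*, the null
distribution of the AUC ratio centers below 1 by roughly 1.64 × CV of the
permutation AUC. With a few thousand domains the CV is small and null
ratios sit at ≈0.95; with only a few hundred domains the envelope premium
is ≈10–15% and the null ratio centers near 0.9. Ratios above 1 therefore
indicate concordance beyond even the upper envelope, at any scale.

**mFC / mCor calling.** mFC is the arithmetic mean of member-gene moderated
log2 fold-changes, tested two-sided: p = (1 + #{perm: |mFC_perm| ≥
|mFC_obs|}) / (1 + n_perm). mCor is the mean over all unordered member
pairs of Pearson correlation across all samples pooled (quantile-normalized
values); pairs with a zero-variance gene are undefined and skipped. Its
null pools, over all domains, the mean correlation between a domain's k
genes and k flanking genes taken closest-first from the two adjacent
domains — k total, split ⌈k/2⌉/⌊k/2⌋ with a short side topped up from the
other adjacent domain only (a k-per-side mode exists as a switch). One
pooled distribution per run; p = (1 + #{null ≥ mCor_obs}) / (1 + pool).
Empirical p-values live on the grid {i/(n+1)} and are never 0. The two
p-values are combined one-sided by Stouffer (z = (z₁ + z₂)/√2,
zᵢ = Φ⁻¹(1 − pᵢ)), BH-adjusted (from-scratch step-up, tested against
independent oracles), and flagged at adjusted p ≤ 0.01. Direction of
activity is reported separately as sign(mFC).

## Companion procedures

*Artificial partitions* span midpoint-to-midpoint of consecutive real
domains, so each straddles exactly one real boundary; artificial domains
whose genes all originate from one real domain are excluded from
comparisons. *Shared boundaries* are matched separately for starts and ends
at a ±2-bin tolerance (40 kb bins by default), each query boundary counting
at most once, and the final percentage is the mean of the two shares.
*Immune domains*: per-gene Pearson correlation of log10(expression + 1)
with sample purity, averaged per domain; the threshold is the 0.05-quantile
of the non-significant (reference) domains' averages and is always
recomputed, never hard-coded. *Family networks* connect same-family genes
sharing a domain, counted on domains where ≥ 50% of genes carry the family
annotation; the null resamples each contiguous cluster of family genes as
an equally long run of contiguous annotated genes on the same chromosome,
rejecting draws in which ≥ 80% of sampled genes share one family, averaged
over 100 resamples. *Conserved regions* join significant domains from
different datasets at ≥ 80% reciprocal base-pair overlap (the stricter,
symmetric reading), take connected components (which collapses duplicated
and nested match sets), keep components with ≥ 3 genes in the intersection
of member domains, and merge regions sharing ≥ 80% of the smaller gene set.

## Differential interactome

Inputs are per-pixel interaction strengths S = −log10(p) from an upstream
contact-significance caller; the module does not fit the contact model.
ΔS = S₁ − S₂ on pixels present in both conditions; the background pools ΔS
for all pixels within a 2 Mb genomic-separation window across chromosomes;
each pixel gets p = (1 + #{|b| ≥ |ΔS|}) / (1 + pool) — the pseudo-count is
applied here too, for consistency with the other empirical p-values, and
≥ in the survival count keeps p grid-valued and ≤ 1 — plus a direction
sign(ΔS) (+1: stronger in condition 1). The tested pixel is included in its
own background (conservative). Upstream coverage equalization between
conditions is assumed, not performed.

## Synthetic data

The generator emulates the structure the method assumes: a fixed domain
partition (5 chromosomes × 40 domains, 3–7 genes each, ≈1000 genes),
log-normal baseline expression (log2 mean 5.0, between-gene sd 1.5,
within-gene noise sd 0.7 — count scale ≈32 so the 5-read/80% filter is
exercised but not dominant), 40 samples per condition, and 5 planted active
domains with a ±1.0 log2 shift in condition 2 plus a shared latent factor
(x = √ρ·f + √(1−ρ)·ε, ρ = 0.5, giving the target pairwise correlation in
expectation). Optional immune domains couple member genes negatively to a
Beta(5, 2) per-sample purity covariate. Values are rounded exp2 of the
Gaussian log2 model; everything is reproducible byte-for-byte from the
seed. Interaction matrices use a distance-decay exponential baseline with
planted gained square blocks.

What the generator does **not** emulate: library-size and gene-length
biases, count overdispersion beyond the log-normal, correlated
domain-to-domain structure (compartment-level coherence), batch effects,
copy-number-driven expression, and realistic Hi-C noise. Passing recovery
tests therefore show the statistics behave as designed under their own
model assumptions — not that the method is robust to every failure mode of
real tumor cohorts.

## Numerical and design choices

- Tests and the examples run the pipeline at 2000 permutations on the
  ≈200-domain cohort; the p-value floor 1/2001 is well below the BH
  threshold at that size, and results at 10,000+ permutations agree. The
  methodological default stays at 10,000.
- Degenerate inputs: all-zero fold-change domains score FCC 0 and are
  flagged; domains with no informative genes are excluded with a warning;
  expression classes with fewer than 2 genes trigger a warning and class
  merging; an empty cross-boundary pool or degenerate (≤ 0 area) null curve
  is an error rather than a silent NaN.
- Condition-swap symmetry: swapping labels negates every lfc and mFC,
  leaves moderated p-values and two-sided empirical p-values unchanged, and
  negates every interactome direction while keeping its p (all tested).
- Whether permutation expression classes should use all samples or one
  condition is an open modeling question; all samples are used, matching
  the pooled-correlation choice for mCor.
- The CLI is a thin layer: every subcommand calls the public library API,
  writes TSV/JSON plus a manifest (tool version, config, input digests,
  seed) sufficient to regenerate its outputs bit-exactly.

## Known limitations

- The mCor cross-boundary null pools within a single run by default;
  pooling across datasets (a larger, smoother null) is available but off,
  trading power for single-run reproducibility.
- The AUC-ratio's null center depends on the number of domains (envelope
  premium above); compare ratios only between runs of similar domain
  counts.
- Small domains dominate fully concordant counts (a 3-gene domain is
  concordant 25% of the time by chance); interpret `frac_fcc1` jointly with
  `frac_fcc1_of_size3`.
- The moderated-variance prior assumes roughly exchangeable gene variances
  after log transformation; strongly bimodal variance structure would call
  for a robust or trended prior, which is not implemented.
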