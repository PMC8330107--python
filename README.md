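# domaindiff

Differential activity of chromatin domains from gene expression.

Chromatin folds into contiguous domains — topologically associating domains
(TADs) and compartment domains — whose member genes tend to be co-regulated.
Given a precomputed domain partition (BED), gene annotations (GFF3/GTF or
TSV), and a genes × samples expression matrix with a two-condition labeling
(tumor vs. normal, mutant vs. wild-type, subtype vs. subtype, ...),
`domaindiff` asks two questions:

1. **Are expression changes more concordant within domains than expected by
   chance?** Each domain *t* with member log2 fold-changes
   LFC(g₁)…LFC(gₙ) gets a fold-change concordance score

   FCC(t) = [ (2/n) Σᵢ δ(sign LFC(gᵢ), −1) − 1 ] · [ 2 Σᵢ |LFC(gᵢ)| δ(sign LFC(gᵢ), −1) / Σᵢ |LFC(gᵢ)| − 1 ]

   the product of a sign-balance and a magnitude-balance term, in [−1, 1]:
   1 when all genes move together, ≈0 for unstructured changes, → −1 when a
   concordant majority is opposed by a few much larger fold-changes. Domains
   are ranked by decreasing FCC and the cumulative-sum curve is compared,
   via the ratio of trapezoidal areas (AUC ratio), with the pointwise
   95th-percentile curve over gene-to-domain permutations stratified by
   expression quintile.

2. **Which domains are differentially active?** Per domain, the mean member
   log2 fold-change (mFC, from a from-scratch empirical-Bayes moderated
   two-sample statistic) and the mean pairwise Pearson correlation of member
   genes on quantile-normalized values (mCor) are each tested against a
   bespoke empirical null — expression-stratified gene permutations for mFC
   (two-sided on |mFC|), and a pooled cross-boundary null for mCor (for each
   domain of k genes, the mean correlation between its genes and the k
   nearest genes beyond its boundaries; one-sided, high = significant).
   Both empirical p-values carry a +1/+1 pseudo-count, are combined with the
   one-sided Stouffer method, BH-adjusted, and a domain is called
   differentially active at adjusted p ≤ 0.01.

Companion analyses cover artificial midpoint (cross-boundary) partitions,
shared-boundary percentages between two partitions, immune-domain flagging
from tumor-purity correlations, gene-family co-domain networks with a
contiguity-preserving resampling null, conserved differentially active
regions across datasets, and a differential-interactome test on per-pixel
contact-significance matrices (ΔS = S₁ − S₂ against a 2 Mb-window empirical
background). A seeded synthetic-data generator plants known active and
immune domains so every statistic has a ground-truth recovery test.

## Worked example

```python
from domaindiff import ActivityConfig, SimConfig, run_domain_activity, simulate_dataset

sim = simulate_dataset(SimConfig(seed=11))   # 200 domains, 5 planted active
res = run_domain_activity(sim.dataset, sim.domains, sim.genes, ActivityConfig(n_perm=2000, seed=11))
print(res.significant.index.tolist())
```

Running `python examples/02_differential_activity.py` prints:

```
191 testable domains, 5 significant at adj. p <= 0.01
planted: ['chr1.d28', 'chr1.d34', 'chr3.d16', 'chr3.d8', 'chr4.d11']
called : ['chr1.d28', 'chr1.d34', 'chr3.d16', 'chr3.d8', 'chr4.d11']
recall 1.00, precision 1.00

           n_genes     mfc    mcor   p_mfc  p_mcor  p_comb   p_adj  direction
chr1.d28         7  0.9395  0.6914  0.0005  0.0052  0.0000  0.0007          1
chr1.d34         5 -0.9449  0.6586  0.0005  0.0052  0.0000  0.0007         -1
...
```

All five planted domains (log2 effect ±1.0, intra-domain correlation 0.5,
40 samples per condition) are recovered with no false positives: their mFC
estimates sit near the planted ±1, their mCor is far above the
cross-boundary null, both empirical p-values are at or near their resolution
floor (1/2001 and 1/(pool+1)), and the BH-adjusted combined p-values clear
the 0.01 threshold. `direction` is the sign of mFC (+1: up in condition 2).

The other scripts in `examples/` demonstrate the concordance/AUC-ratio
analysis, the companion analyses, and the differential interactome, each
printing a short annotated report. The same capabilities are exposed as a
thin CLI: `domaindiff simulate | fcc | activity | aux | diffint` (see
`domaindiff --help`).

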