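"""Per-domain differential-activity calling.

Two statistics are computed per chromatin domain:

* **mFC** — the mean log2 fold-change of the member genes between conditions,
  tested two-sided against gene-to-domain permutations stratified by
  expression level;
* **mCor** — the mean pairwise Pearson correlation of member genes across all
  samples (on quantile-normalized values), tested one-sided (high = tight
  co-expression) against a pooled cross-boundary null: for each domain of k
  genes, the mean correlation between its genes and the k nearest genes
  beyond its boundaries.

Empirical p-values carry a +1/+1 pseudo-count so they lie on the grid
``{i/(n+1)}`` and are never 0. The two p-values are combined with the
one-sided Stouffer method and adjusted by Benjamini-Hochberg; a domain is
called differentially active at adjusted p <= alpha (default 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import expression_classes, permuted_lfc_matrix
from .diffexpr import bh_adjust, compute_lfc, moderated_de_test
from .genome import (
    DomainGeneMap,
    ExpressionDataset,
    GenomicDomain,
    assign_genes_to_domains,
    filter_domains,
    filter_genes_by_coverage,
    quantile_normalize,
    upper_quartile_scale,
)

logger = logging.getLogger(__name__)


@dataclass
class ActivityConfig:
    """Tunable parameters of the differential-activity pipeline."""

    alpha: float = 0.01
    n_perm: int = 10_000
    n_classes: int = 5
    min_genes: int = 3
    max_genes_quantile: float = 0.99
    coverage_min_reads: float = 5.0
    coverage_min_sample_frac: float = 0.80
    counts_input: bool = True  # apply coverage filter + upper-quartile scaling
    moderated: bool = True  # empirical-Bayes moderated lfc; else plain mean diff
    flank_per_side: bool = False  # cross-boundary null: k per side instead of k total
    seed: int = 0


@dataclass
class CrossBoundaryNull:
    """Pooled distribution of cross-boundary mean correlations."""

    values: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.values.size


def domain_mfc(lfc: pd.Series, gmap: DomainGeneMap) -> pd.Series:
    """Mean member-gene log2 fold-change per domain."""
    out = {}
    for d, genes in gmap.items():
        vals = lfc.loc[genes].to_numpy()
        if vals.size == 0:
            logger.warning("domain %s has no informative genes; excluded", d)
            continue
        out[d] = float(vals.mean())
    return pd.Series(out, name="mfc")


def _pairwise_corr(x: np.ndarray) -> np.ndarray:
    """Correlation matrix of rows; zero-variance rows yield NaN entries."""
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c = np.atleast_2d(c)
    bad = sd == 0
    c[bad, :] = np.nan
    c[:, bad] = np.nan
    return c


def domain_mcor(ds_qnorm: ExpressionDataset, gmap: DomainGeneMap) -> pd.Series:
    """Mean pairwise Pearson correlation of member genes across all samples.

    Pairs involving a zero-variance gene are undefined and skipped.
    """
    out = {}
    for d, genes in gmap.items():
        x = ds_qnorm.values.loc[genes].to_numpy(dtype=float)
        if x.shape[0] < 2:
            continue
        c = _pairwise_corr(x)
        iu = np.triu_indices(x.shape[0], k=1)
        vals = c[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("domain %s: all gene pairs undefined (zero variance)", d)
            continue
        out[d] = float(vals.mean())
    return pd.Series(out, name="mcor")


def empirical_p_mfc(
    mfc_obs: pd.Series,
    ds: ExpressionDataset,
    gmap: DomainGeneMap,
    lfc: pd.Series,
    n_perm: int = 10_000,
    n_classes: int = 5,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Two-sided empirical p per domain from stratified gene permutations.

    ``p = (1 + #{perm: |mFC_perm| >= |mFC_obs|}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d gives a p-value floor of %.3g", n_perm, 1 / (n_perm + 1))
    genes = gmap.all_genes()
    classes = expression_classes(ds, genes, n_classes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = permuted_lfc_matrix(lfc.loc[genes].to_numpy(), classes, n_perm, rng)
    gene_index = {g: i for i, g in enumerate(genes)}
    out = {}
    for d in mfc_obs.index:
        idx = np.array([gene_index[g] for g in gmap[d]])
        perm_mfc = perm[:, idx].mean(axis=1)
        hits = int(np.sum(np.abs(perm_mfc) >= abs(mfc_obs[d])))
        out[d] = (1 + hits) / (1 + n_perm)
    return pd.Series(out, name="p_mfc")


def _flank_genes(
    gmap: DomainGeneMap,
    ordered_domains: list[GenomicDomain],
    i: int,
    k: int,
    per_side: bool,
) -> list[str]:
    """Pick flanking genes for domain ``i`` from its two adjacent domains.

    Genes are taken closest-to-boundary first: the tail of the left neighbor's
    TSS-ordered gene list and the head of the right neighbor's. ``k`` genes
    total are split ceil/floor between the sides; a short side is topped up
    from the other adjacent domain only. With ``per_side`` the target is k
    genes from each side.
    """
    left = ordered_domains[i - 1].domain_id if i > 0 else None
    right = ordered_domains[i + 1].domain_id if i + 1 < len(ordered_domains) else None
    left_pool = list(reversed(gmap[left])) if left and left in gmap else []
    right_pool = list(gmap[right]) if right and right in gmap else []
    if per_side:
        return left_pool[:k] + right_pool[:k]
    want_left = (k + 1) // 2
    want_right = k // 2
    take_left = min(want_left, len(left_pool))
    take_right = min(want_right, len(right_pool))
    # redistribute shortfall to the other side
    take_right = min(len(right_pool), take_right + (want_left - take_left))
    take_left = min(len(left_pool), take_left + (want_right + want_left - take_left - take_right))
    return left_pool[:take_left] + right_pool[:take_right]


def build_cross_boundary_null(
    ds_qnorm: ExpressionDataset,
    gmap: DomainGeneMap,
    domains: list[GenomicDomain],
    per_side: bool = False,
) -> CrossBoundaryNull:
    """Pooled cross-boundary mean correlations over all domains.

    For each domain D with k genes, k flanking genes are selected from the
    adjacent domains (closest to the boundaries first) and the mean of all
    D-gene x flank-gene correlations contributes one value to the pool.
    Domains with no flanking genes are skipped.
    """
    expr = ds_qnorm.values
    by_chrom: dict[str, list[GenomicDomain]] = {}
    for d in sorted(domains, key=lambda d: (d.chrom, d.start)):
        by_chrom.setdefault(d.chrom, []).append(d)
    pool: list[float] = []
    provenance: list[str] = []
    for chrom, ds_list in by_chrom.items():
        for i, dom in enumerate(ds_list):
            if dom.domain_id not in gmap:
                continue
            genes = gmap[dom.domain_id]
            k = len(genes)
            flank = _flank_genes(gmap, ds_list, i, k, per_side)
            if not flank:
                logger.debug("domain %s: no flanking genes; skipped", dom.domain_id)
                continue
            a = expr.loc[genes].to_numpy(dtype=float)
            b = expr.loc[flank].to_numpy(dtype=float)
            c = _cross_corr(a, b)
            vals = c[np.isfinite(c)]
            if vals.size == 0:
                continue
            pool.append(float(vals.mean()))
            provenance.append(dom.domain_id)
    return CrossBoundaryNull(np.array(pool), provenance)


def _cross_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlations between every row of ``a`` and every row of ``b``."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = az @ bz.T / np.outer(asd, bsd)
    return c


def empirical_p_mcor(mcor_obs: pd.Series, null: CrossBoundaryNull) -> pd.Series:
    """One-sided empirical p: high mCor relative to the cross-boundary pool.

    ``p = (1 + #{v in null: v >= mCor_obs}) / (1 + |null|)``.
    """
    if len(null) == 0:
        raise ValueError("empty cross-boundary null")
    sorted_null = np.sort(null.values)
    n = sorted_null.size
    out = {}
    for d, obs in mcor_obs.items():
        ge = n - int(np.searchsorted(sorted_null, obs, side="left"))
        out[d] = (1 + ge) / (1 + n)
    return pd.Series(out, name="p_mcor")


def stouffer_combine(p_mfc: pd.Series, p_mcor: pd.Series) -> pd.Series:
    """One-sided Stouffer combination of two p-values.

    ``z_i = Phi^-1(1 - p_i); p_comb = 1 - Phi((z_1 + z_2)/sqrt(2))``, clipped
    into (0, 1].
    """
    for p in (p_mfc, p_mcor):
        if (p <= 0).any():
            raise ValueError("p-values must be > 0 for Stouffer combination")
    z = stats.norm.isf(p_mfc.to_numpy()) + stats.norm.isf(p_mcor.to_numpy())
    p = stats.norm.sf(z / np.sqrt(2.0))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.Series(p, index=p_mfc.index, name="p_comb")


@dataclass
class ActivityResult:
    """Output bundle of the differential-activity pipeline."""

    table: pd.DataFrame
    gmap: DomainGeneMap
    lfc: pd.Series
    cross_boundary_null: CrossBoundaryNull
    config: ActivityConfig

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def prepare_dataset(
    ds: ExpressionDataset, cfg: ActivityConfig
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Pre-processing: coverage filter, scaling, and the two working scales.

    Returns ``(ds_classes, ds_log, ds_qnorm)``: the filtered expression used
    for building expression classes, its log2(upper-quartile-scaled + 1)
    transform for differential expression, and the quantile-normalized log
    values for correlations.
    """
    if cfg.counts_input:
        ds = filter_genes_by_coverage(ds, cfg.coverage_min_reads, cfg.coverage_min_sample_frac)
        scaled = upper_quartile_scale(ds)
    else:
        scaled = ds
    ds_log = scaled.with_values(np.log2(scaled.values + 1.0))
    ds_qnorm = quantile_normalize(ds_log)
    return ds, ds_log, ds_qnorm


def run_domain_activity(
    ds: ExpressionDataset,
    domains: list[GenomicDomain],
    genes,
    cfg: ActivityConfig | None = None,
) -> ActivityResult:
    """Full differential-activity pipeline.

    Filters genes and domains, computes gene-level fold-changes, the mFC and
    mCor statistics, their empirical p-values against the permutation and
    cross-boundary nulls, Stouffer-combined and BH-adjusted p-values, and
    flags domains significant at ``cfg.alpha``.
    """
    cfg = cfg or ActivityConfig()
    ds_raw, ds_log, ds_qnorm = prepare_dataset(ds, cfg)
    gmap = assign_genes_to_domains(genes, domains)
    kept_genes = set(ds_raw.genes)
    gmap = DomainGeneMap(
        {d: [g for g in gs if g in kept_genes] for d, gs in gmap.items()},
        list(gmap.domains.values()),
        unassigned=gmap.unassigned,
    )
    gmap = filter_domains(gmap, cfg.min_genes, cfg.max_genes_quantile)
    keep = [g for g in ds_raw.genes if g in set(gmap.all_genes())]
    ds_classes = ds_raw.with_values(ds_raw.values.loc[keep])
    ds_log = ds_log.with_values(ds_log.values.loc[keep])
    ds_qnorm = ds_qnorm.with_values(ds_qnorm.values.loc[keep])

    if cfg.moderated:
        de = moderated_de_test(ds_log)
        lfc = de["lfc"]
    else:
        lfc = compute_lfc(ds_log, pseudocount=0.0)

    rng = np.random.default_rng(cfg.seed)
    mfc = domain_mfc(lfc, gmap)
    mcor = domain_mcor(ds_qnorm, gmap)
    p_mfc = empirical_p_mfc(
        mfc, ds_classes, gmap, lfc, n_perm=cfg.n_perm, n_classes=cfg.n_classes,
        seed=np.random.default_rng(rng.integers(2**31)),
    )
    null = build_cross_boundary_null(
        ds_qnorm, gmap, list(gmap.domains.values()), per_side=cfg.flank_per_side
    )
    p_mcor = empirical_p_mcor(mcor, null)

    idx = mfc.index.intersection(mcor.index)
    p_comb = stouffer_combine(p_mfc.loc[idx], p_mcor.loc[idx])
    p_adj = pd.Series(bh_adjust(p_comb.to_numpy()), index=idx, name="p_adj")

    counts = gmap.gene_counts()
    doms = gmap.domains
    table = pd.DataFrame(
        {
            "chrom": [doms[d].chrom for d in idx],
            "start": [doms[d].start for d in idx],
            "end": [doms[d].end for d in idx],
            "n_genes": [counts[d] for d in idx],
            "mfc": mfc.loc[idx],
            "mcor": mcor.loc[idx],
            "p_mfc": p_mfc.loc[idx],
            "p_mcor": p_mcor.loc[idx],
            "p_comb": p_comb,
            "p_adj": p_adj,
        },
        index=idx,
    )
    table["direction"] = np.sign(table["mfc"]).astype(int)
    table["significant"] = table["p_adj"] <= cfg.alpha
    table.index.name = "domain_id"
    table = table.sort_values(["p_adj", "p_comb"])
    return ActivityResult(table, gmap, lfc, null, cfg)
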