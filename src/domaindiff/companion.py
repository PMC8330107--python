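"""Companion analyses around the differential-activity caller.

* artificial cross-boundary partitions (midpoint-to-midpoint domains);
* shared-boundary ratio between two domain partitions;
* immune-domain flagging from tumor-purity correlations;
* gene-family co-domain networks with a contiguity-preserving null;
* conserved differentially active regions across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import DomainGeneMap, ExpressionDataset, GeneRecord, GenomicDomain

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Artificial cross-boundary partitions
# ---------------------------------------------------------------------------

def artificial_partition(domains: Sequence[GenomicDomain]) -> list[GenomicDomain]:
    """Midpoint-to-midpoint partition: each artificial domain straddles exactly
    one real domain boundary.

    Artificial domain i on a chromosome spans ``[mid(d_i), mid(d_{i+1}))``;
    chromosomes with fewer than 2 real domains contribute none.
    """
    by_chrom: dict[str, list[GenomicDomain]] = {}
    for d in sorted(domains, key=lambda d: (d.chrom, d.start)):
        by_chrom.setdefault(d.chrom, []).append(d)
    out: list[GenomicDomain] = []
    for chrom, ds in by_chrom.items():
        for i in range(len(ds) - 1):
            out.append(
                GenomicDomain(chrom, ds[i].mid, ds[i + 1].mid, f"A{chrom}.{i}")
            )
    return out


def filter_cross_boundary(
    art_map: DomainGeneMap, real_map: DomainGeneMap
) -> DomainGeneMap:
    """Drop artificial domains whose genes all come from one real domain.

    The comparison is meaningful only where an artificial domain mixes genes
    from the two real domains it straddles.
    """
    gene_to_real: dict[str, str] = {}
    for d, gs in real_map.items():
        for g in gs:
            gene_to_real[g] = d
    keep = []
    for d, gs in art_map.items():
        sources = {gene_to_real.get(g) for g in gs} - {None}
        if len(sources) >= 2:
            keep.append(d)
    return art_map.subset(keep)


# ---------------------------------------------------------------------------
# Shared boundaries
# ---------------------------------------------------------------------------

def shared_boundary_ratio(
    domains_a: Sequence[GenomicDomain],
    domains_b: Sequence[GenomicDomain],
    bin_size: int = 40_000,
    tolerance_bins: int = 2,
) -> float:
    """Fraction of boundaries shared between two partitions.

    Start and end boundaries are matched separately from A into B: a boundary
    in bin X matches if B has a same-kind boundary within ``[X - t, X + t]``
    bins. Each query boundary counts at most once; the final ratio is the
    mean of the start-share and end-share.
    """
    if not domains_a or not domains_b:
        raise ValueError("empty partition")

    def bins(doms: Sequence[GenomicDomain], attr: str) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for d in doms:
            out.setdefault(d.chrom, []).append(getattr(d, attr) // bin_size)
        return {c: np.unique(v) for c, v in out.items()}

    shares = []
    for attr in ("start", "end"):
        qa, qb = bins(domains_a, attr), bins(domains_b, attr)
        total = hit = 0
        for chrom, xs in qa.items():
            ys = qb.get(chrom, np.array([], dtype=int))
            total += xs.size
            if ys.size == 0:
                continue
            ys = np.sort(ys)
            j = np.searchsorted(ys, xs)
            left = np.where(j > 0, np.abs(xs - ys[np.maximum(j - 1, 0)]), np.inf)
            right = np.where(j < ys.size, np.abs(ys[np.minimum(j, ys.size - 1)] - xs), np.inf)
            hit += int(np.sum(np.minimum(left, right) <= tolerance_bins))
        shares.append(hit / total if total else 0.0)
    return float(np.mean(shares))


# ---------------------------------------------------------------------------
# Immune domains
# ---------------------------------------------------------------------------

def flag_immune_domains(
    ds: ExpressionDataset,
    gmap: DomainGeneMap,
    purity: Mapping[str, float],
    reference: set[str],
    quantile_cut: float = 0.05,
) -> pd.DataFrame:
    """Flag domains whose expression tracks immune infiltration.

    Per gene, the Pearson correlation of log10(expression + 1) with sample
    purity is computed across the samples with a purity score; these
    correlations are averaged per domain. The flagging threshold is the
    ``quantile_cut``-quantile of the averages over the ``reference`` set
    (the non-significantly differentially active domains): a low average
    correlation with purity marks expression driven by non-tumor
    (immune/stromal) content. Domains at or below the threshold are flagged.
    """
    samples = [s for s in ds.samples if s in purity and np.isfinite(purity[s])]
    if len(samples) < 0.8 * len(ds.samples):
        logger.warning("purity available for < 80%% of samples (%d/%d)",
                       len(samples), len(ds.samples))
    pur = np.array([purity[s] for s in samples], dtype=float)
    if np.std(pur) == 0:
        raise ValueError("constant purity vector: correlations undefined")
    x = np.log10(ds.values[samples].to_numpy(dtype=float) + 1.0)
    xz = x - x.mean(axis=1, keepdims=True)
    pz = pur - pur.mean()
    denom = np.sqrt((xz**2).sum(axis=1)) * np.sqrt((pz**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        gene_cor = pd.Series(xz @ pz / denom, index=ds.values.index)
    dom_cor = {}
    for d, genes in gmap.items():
        vals = gene_cor.loc[genes].dropna()
        if len(vals):
            dom_cor[d] = float(vals.mean())
    dom_cor = pd.Series(dom_cor, name="purity_cor")
    ref_vals = dom_cor.loc[[d for d in dom_cor.index if d in reference]]
    if ref_vals.empty:
        raise ValueError("no reference domains with a purity correlation")
    threshold = float(np.quantile(ref_vals.to_numpy(), quantile_cut))
    out = pd.DataFrame({"purity_cor": dom_cor})
    out["immune"] = out["purity_cor"] <= threshold
    out.attrs["threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# Gene-family networks
# ---------------------------------------------------------------------------

@dataclass
class FamilyNetwork:
    """Co-domain network of one gene family: observed vs expected edge count."""

    family: str
    nodes: list[str]
    observed_edges: int
    expected_edges: float
    edges: list[tuple[str, str]] = field(default_factory=list)


def resolve_families(annotations: Mapping[str, str]) -> dict[str, str]:
    """Keep the first-level (most general) family of a '|'-separated annotation."""
    return {g: fam.split("|")[0] for g, fam in annotations.items() if fam}


def _qualifying_domains(
    gmap: DomainGeneMap, fam_of: Mapping[str, str], family: str, min_frac: float
) -> list[str]:
    out = []
    for d, genes in gmap.items():
        if not genes:
            continue
        n_fam = sum(1 for g in genes if fam_of.get(g) == family)
        if n_fam / len(genes) >= min_frac:
            out.append(d)
    return out


def count_family_edges(
    gmap: DomainGeneMap, members: set[str], domains: Sequence[str]
) -> list[tuple[str, str]]:
    edges = []
    for d in domains:
        in_dom = [g for g in gmap[d] if g in members]
        edges.extend(
            (in_dom[i], in_dom[j])
            for i in range(len(in_dom))
            for j in range(i + 1, len(in_dom))
        )
    return edges


def _contiguous_clusters(positions: list[int]) -> list[list[int]]:
    """Split sorted index positions into runs of consecutive integers."""
    clusters: list[list[int]] = []
    for p in positions:
        if clusters and p == clusters[-1][-1] + 1:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def family_network_enrichment(
    gmap: DomainGeneMap,
    genes: Sequence[GeneRecord],
    families: Mapping[str, str],
    n_perm: int = 100,
    min_domain_frac: float = 0.50,
    same_family_limit: float = 0.80,
    seed: int | np.random.Generator = 0,
) -> dict[str, FamilyNetwork]:
    """Observed vs expected co-domain edges per gene family.

    Edges connect family members assigned to the same domain, counted only on
    domains where at least ``min_domain_frac`` of the genes carry the family
    annotation. The null preserves chromosome representation and gene
    contiguity: each contiguous cluster of k family genes (on the TSS-ordered
    list of annotated genes of its chromosome) is replaced by a random run of
    k contiguous annotated genes from the same chromosome; a draw is rejected
    when ``same_family_limit`` or more of the sampled genes share one family.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fam_of = resolve_families(families)
    annotated = [g for g in genes if g.gene_id in fam_of]
    # TSS-ordered annotated genes per chromosome
    per_chrom: dict[str, list[str]] = {}
    for g in sorted(annotated, key=lambda g: (g.chrom, g.tss, g.gene_id)):
        per_chrom.setdefault(g.chrom, []).append(g.gene_id)
    pos_of = {g: (c, i) for c, lst in per_chrom.items() for i, g in enumerate(lst)}
    placed = {g for g in fam_of if g in pos_of}

    results: dict[str, FamilyNetwork] = {}
    for family in sorted(set(fam_of.values())):
        members = sorted(g for g in placed if fam_of[g] == family)
        if len(members) < 2:
            continue
        qual = _qualifying_domains(gmap, fam_of, family, min_domain_frac)
        edges = count_family_edges(gmap, set(members), qual)
        # clusters of contiguous member positions per chromosome
        clusters: list[tuple[str, int]] = []  # (chrom, length)
        for chrom in per_chrom:
            positions = sorted(pos_of[g][1] for g in members if pos_of[g][0] == chrom)
            clusters.extend((chrom, len(run)) for run in _contiguous_clusters(positions))
        exp_counts = []
        for _ in range(n_perm):
            sampled: list[str] = []
            for chrom, k in clusters:
                lst = per_chrom[chrom]
                if len(lst) < k:
                    sampled.extend(lst)
                    continue
                for _attempt in range(100):
                    start = int(rng.integers(0, len(lst) - k + 1))
                    run = lst[start:start + k]
                    fams = [fam_of[g] for g in run]
                    top = max(fams.count(f) for f in set(fams))
                    if top / k < same_family_limit or k == 1:
                        break
                sampled.extend(run)
            exp_counts.append(len(count_family_edges(gmap, set(sampled), qual)))
        results[family] = FamilyNetwork(
            family=family,
            nodes=members,
            observed_edges=len(edges),
            expected_edges=float(np.mean(exp_counts)) if exp_counts else float("nan"),
            edges=edges,
        )
    return results


# ---------------------------------------------------------------------------
# Conserved regions
# ---------------------------------------------------------------------------

@dataclass
class ConservedRegion:
    chrom: str
    start: int
    end: int
    datasets: set[str]
    genes: set[str]

    @property
    def support(self) -> int:
        return len(self.datasets)


def _reciprocal_overlap(a: GenomicDomain, b: GenomicDomain, frac: float) -> bool:
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov > 0 and ov >= frac * len(a) and ov >= frac * len(b)


def conserved_regions(
    significant_sets: Mapping[str, Sequence[GenomicDomain]],
    gene_sets: Mapping[str, Mapping[str, Sequence[str]]],
    overlap_frac: float = 0.80,
    min_genes: int = 3,
    merge_gene_frac: float = 0.80,
) -> list[ConservedRegion]:
    """Regions differentially active across datasets.

    All-vs-all matching of significant domains from different datasets at
    >= ``overlap_frac`` reciprocal base-pair overlap; each maximal match set
    spans min-start to max-end, keeps the genes at the intersection of its
    member domains, and is retained with >= ``min_genes`` such genes.
    Regions sharing >= ``merge_gene_frac`` of intersect genes are merged.
    Nested/duplicated match sets collapse into their maximal set.
    """
    if len(significant_sets) < 2:
        raise ValueError("need >= 2 datasets")
    items: list[tuple[str, GenomicDomain]] = [
        (name, d) for name, doms in significant_sets.items() for d in doms
    ]
    n = len(items)
    # connected components of the reciprocal-overlap graph (transitive closure
    # collapses duplicated and nested match sets into one region)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if items[i][0] != items[j][0] and _reciprocal_overlap(
                items[i][1], items[j][1], overlap_frac
            ):
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    regions: list[ConservedRegion] = []
    for members in groups.values():
        names = {items[i][0] for i in members}
        if len(names) < 2:
            continue
        doms = [items[i][1] for i in members]
        gene_lists = [
            set(gene_sets[items[i][0]].get(items[i][1].domain_id, ()))
            for i in members
        ]
        intersect = set.intersection(*gene_lists) if gene_lists else set()
        if len(intersect) < min_genes:
            continue
        regions.append(
            ConservedRegion(
                chrom=doms[0].chrom,
                start=min(d.start for d in doms),
                end=max(d.end for d in doms),
                datasets=names,
                genes=intersect,
            )
        )

    # merge regions sharing >= merge_gene_frac of their intersect genes
    merged = True
    while merged:
        merged = False
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                a, b = regions[i], regions[j]
                if a.chrom != b.chrom:
                    continue
                common = a.genes & b.genes
                small = min(len(a.genes), len(b.genes))
                if small and len(common) / small >= merge_gene_frac:
                    regions[i] = ConservedRegion(
                        a.chrom,
                        min(a.start, b.start),
                        max(a.end, b.end),
                        a.datasets | b.datasets,
                        a.genes | b.genes,
                    )
                    del regions[j]
                    merged = True
                    break
            if merged:
                break
    return sorted(regions, key=lambda r: (r.chrom, r.start))
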