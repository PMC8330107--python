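"""Synthetic domains, genes, expression, purity and interaction matrices.

The generator plants known structure so every statistic has a ground-truth
recovery test:

* **active domains** shift all member genes by ``effect_lfc`` (log2 units) in
  condition 2 and share a latent factor inducing intra-domain correlation
  ``intra_domain_rho`` (``x = sqrt(rho) * f + sqrt(1 - rho) * eps`` so the
  pairwise correlation of the Gaussian part equals rho in expectation);
* **immune domains** couple member genes negatively to a per-sample purity
  covariate;
* all other domains are independent noise around a gene-specific baseline.

Expression is emitted on a count-like scale (rounded exp2 of the Gaussian
log2 model) so the read-coverage filter is exercised. Everything is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import ExpressionDataset, GeneRecord, GenomicDomain
from .interactome import InteractionStrengthMatrix


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults describe a small two-condition cohort: 200 domains over 5
    chromosomes with 3-7 genes each (~1000 genes), 40 samples per condition,
    5 planted active domains with a one-unit log2 shift and 0.5 intra-domain
    correlation, moderate biological noise.
    """

    n_chrom: int = 5
    domains_per_chrom: int = 40
    genes_per_domain: tuple[int, int] = (3, 7)
    samples_per_condition: int = 40
    planted_active_domains: int = 5
    effect_lfc: float = 1.0
    intra_domain_rho: float = 0.5
    immune_domains: int = 0
    immune_coupling: float = 1.0
    noise_sd: float = 0.7
    base_log2_mean: float = 5.0
    gene_level_sd: float = 1.5
    gene_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.intra_domain_rho < 1):
            raise ValueError("intra_domain_rho must be in [0, 1)")
        for name in ("n_chrom", "domains_per_chrom", "samples_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.genes_per_domain
        if lo < 1 or hi < lo:
            raise ValueError("genes_per_domain must be a valid (lo, hi) range")


@dataclass
class SimulatedDataset:
    domains: list[GenomicDomain]
    genes: list[GeneRecord]
    dataset: ExpressionDataset
    purity: dict[str, float]
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate a full fixture bundle with planted active/immune domains."""
    rng = np.random.default_rng(cfg.seed)
    domains: list[GenomicDomain] = []
    genes: list[GeneRecord] = []
    domain_genes: dict[str, list[str]] = {}
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        pos = 0
        for d in range(cfg.domains_per_chrom):
            k = int(rng.integers(cfg.genes_per_domain[0], cfg.genes_per_domain[1] + 1))
            length = (k + 1) * cfg.gene_spacing
            dom = GenomicDomain(chrom, pos, pos + length, f"{chrom}.d{d}")
            domains.append(dom)
            ids = []
            for i in range(k):
                gid = f"g_{chrom}_{d}_{i}"
                strand = "+" if (i % 2 == 0) else "-"
                tss = pos + (i + 1) * cfg.gene_spacing - cfg.gene_spacing // 2
                if strand == "+":
                    start, end = tss, tss + 2000
                else:
                    start, end = tss - 1999, tss + 1
                genes.append(GeneRecord(gid, chrom, strand, start, end))
                ids.append(gid)
            domain_genes[dom.domain_id] = ids
            pos += length
    n_genes = len(genes)
    if cfg.planted_active_domains + cfg.immune_domains > len(domains):
        raise ValueError("more planted domains than domains available")

    dom_ids = [d.domain_id for d in domains]
    special = rng.choice(len(dom_ids), cfg.planted_active_domains + cfg.immune_domains,
                         replace=False)
    active = [dom_ids[i] for i in special[: cfg.planted_active_domains]]
    immune = [dom_ids[i] for i in special[cfg.planted_active_domains:]]
    # alternate planted direction so both signs of activity occur
    direction = {d: (1 if i % 2 == 0 else -1) for i, d in enumerate(active)}

    n1 = n2 = cfg.samples_per_condition
    samples = [f"s{i}_c1" for i in range(n1)] + [f"s{i}_c2" for i in range(n2)]
    condition = {s: ("cond1" if s.endswith("c1") else "cond2") for s in samples}
    n_s = n1 + n2

    mu = cfg.base_log2_mean + cfg.gene_level_sd * rng.standard_normal(n_genes)
    log2x = np.tile(mu[:, None], (1, n_s))
    eps = rng.standard_normal((n_genes, n_s)) * cfg.noise_sd
    gene_row = {g.gene_id: i for i, g in enumerate(genes)}
    purity = dict(zip(samples, rng.beta(5, 2, size=n_s)))
    pur = np.array([purity[s] for s in samples])
    pur_z = (pur - pur.mean()) / pur.std()

    rho = cfg.intra_domain_rho
    for d in active:
        rows = [gene_row[g] for g in domain_genes[d]]
        f = rng.standard_normal(n_s) * cfg.noise_sd
        eps[rows, :] = np.sqrt(rho) * f[None, :] + np.sqrt(1 - rho) * eps[rows, :]
        log2x[rows, n1:] += direction[d] * cfg.effect_lfc
    for d in immune:
        rows = [gene_row[g] for g in domain_genes[d]]
        log2x[rows, :] += -cfg.immune_coupling * pur_z[None, :]
    log2x = log2x + eps

    counts = np.maximum(np.round(np.exp2(log2x)), 0.0)
    values = pd.DataFrame(counts, index=[g.gene_id for g in genes], columns=samples)
    ds = ExpressionDataset(values, condition)

    rows = []
    for d in dom_ids:
        if d in direction:
            rows.append((d, "active_up" if direction[d] > 0 else "active_down",
                         direction[d] * cfg.effect_lfc))
        elif d in immune:
            rows.append((d, "immune", cfg.immune_coupling))
        else:
            rows.append((d, "null", 0.0))
    truth = pd.DataFrame(rows, columns=["domain_id", "type", "effect"]).set_index("domain_id")
    return SimulatedDataset(domains, genes, ds, purity, truth, cfg)


def shuffle_condition_labels(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Randomly reassign samples to the two conditions (global-null control)."""
    rng = np.random.default_rng(seed)
    labels = [ds.condition[s] for s in ds.samples]
    shuffled = rng.permutation(labels)
    new = ExpressionDataset(ds.values, dict(zip(ds.samples, shuffled)))
    new.conditions = ds.conditions
    return new


@dataclass
class SimulatedInteractions:
    m1: InteractionStrengthMatrix
    m2: InteractionStrengthMatrix
    truth: pd.DataFrame  # planted blocks: chrom, bin_lo, bin_hi, gain (in m1)


def simulate_interaction_pair(
    n_bins: int = 100,
    bin_size: int = 40_000,
    chrom: str = "chr1",
    planted_blocks: int = 1,
    block_bins: int = 5,
    gain: float = 2.0,
    seed: int = 0,
) -> SimulatedInteractions:
    """Two interaction-strength matrices with planted gained blocks in m1.

    The baseline is a distance-decay exponential strength plus independent
    noise per condition; planted square blocks add ``gain`` to condition 1.
    """
    rng = np.random.default_rng(seed)
    i, j = np.indices((n_bins, n_bins))
    sep = np.abs(i - j)
    scale = 2.0 / (1.0 + sep / 10.0)

    def sym_noise() -> np.ndarray:
        x = rng.exponential(scale=scale)
        return np.triu(x) + np.triu(x, 1).T

    s1 = sym_noise()
    s2 = sym_noise()
    rows = []
    for b in range(planted_blocks):
        lo = int(rng.integers(0, n_bins - block_bins + 1))
        hi = lo + block_bins
        s1[lo:hi, lo:hi] += gain
        rows.append((chrom, lo, hi - 1, gain))
    truth = pd.DataFrame(rows, columns=["chrom", "bin_lo", "bin_hi", "gain"])
    return SimulatedInteractions(
        InteractionStrengthMatrix(chrom, bin_size, s1),
        InteractionStrengthMatrix(chrom, bin_size, s2),
        truth,
    )


# ---------------------------------------------------------------------------
# Fixture writers (the exact formats the readers consume)
# ---------------------------------------------------------------------------

def write_fixture_bundle(sim: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write BED domains, gene TSV, expression TSV, conditions, purity, truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "domains": out / "domains.bed",
        "genes": out / "genes.tsv",
        "expression": out / "expression.tsv",
        "conditions": out / "conditions.tsv",
        "purity": out / "purity.tsv",
        "truth": out / "truth.tsv",
    }
    with open(paths["domains"], "w") as fh:
        for d in sim.domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.domain_id}\n")
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.start, g.end) for g in sim.genes],
        columns=["gene_id", "chrom", "strand", "start", "end"],
    ).to_csv(paths["genes"], sep="\t", index=False)
    sim.dataset.values.to_csv(paths["expression"], sep="\t")
    with open(paths["conditions"], "w") as fh:
        for s in sim.dataset.samples:
            fh.write(f"{s}\t{sim.dataset.condition[s]}\n")
    with open(paths["purity"], "w") as fh:
        for s, v in sim.purity.items():
            fh.write(f"{s}\t{v:.6f}\n")
    sim.truth.to_csv(paths["truth"], sep="\t")
    return paths
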