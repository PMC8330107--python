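"""Fold-change concordance (FCC) of chromatin domains and the AUC-ratio test.

The FCC score of a domain with member log2 fold-changes ``l_1..l_n`` is the
product of a sign-balance and a magnitude-balance term::

    FCC = (2/n * #{l_i < 0} - 1) * (2 * sum(|l_i| for l_i < 0) / sum(|l_i|) - 1)

It equals 1 when all genes move in the same direction, sits near 0 for mixed
signs of comparable magnitudes, and approaches -1 when a concordant majority
is opposed by a few genes of much larger fold-change.

Genome-wide concordance is summarized by ranking domains by decreasing FCC,
taking the cumulative sum, and comparing its area under the curve with that
of a null curve built from gene-to-domain permutations stratified by
expression level (the pointwise 95th percentile over permutations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import DomainGeneMap, ExpressionDataset

logger = logging.getLogger(__name__)


def fcc_score(lfc) -> float:
    """FCC of one domain from its member genes' log2 fold-changes.

    Genes with fold-change exactly 0 carry no sign and are excluded; an
    all-zero vector yields the degenerate value 0.
    """
    lfc = np.asarray(lfc, dtype=float)
    lfc = lfc[lfc != 0]
    n = lfc.size
    if n == 0:
        return 0.0
    neg = lfc < 0
    count_term = 2.0 * neg.sum() / n - 1.0
    absl = np.abs(lfc)
    mag_term = 2.0 * absl[neg].sum() / absl.sum() - 1.0
    return float(count_term * mag_term)


def fcc_scores_matrix(lfc_rows: np.ndarray) -> np.ndarray:
    """Row-wise FCC for a (n_rows, n_genes) matrix of fold-change vectors.

    Vectorized counterpart of :func:`fcc_score` used by the permutation
    machinery; zero entries are excluded per row.
    """
    x = np.asarray(lfc_rows, dtype=float)
    nonzero = x != 0
    n = nonzero.sum(axis=1)
    neg = x < 0
    absx = np.abs(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        count_term = 2.0 * neg.sum(axis=1) / n - 1.0
        mag_term = 2.0 * (absx * neg).sum(axis=1) / absx.sum(axis=1) - 1.0
    out = count_term * mag_term
    return np.where(n > 0, out, 0.0)


def domain_fcc(lfc: pd.Series, gmap: DomainGeneMap) -> pd.Series:
    """FCC per domain from a per-gene lfc vector."""
    return pd.Series(
        {d: fcc_score(lfc.loc[genes].to_numpy()) for d, genes in gmap.items()},
        name="fcc",
    )


def ranked_cumsum(fcc_by_domain) -> np.ndarray:
    """Cumulative sum of FCC values ranked in decreasing order.

    ``curve[k-1]`` is the sum of the k largest FCC values.
    """
    vals = np.asarray(fcc_by_domain, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one domain")
    return np.cumsum(np.sort(vals)[::-1])


def expression_classes(
    ds: ExpressionDataset, genes: list[str], n_classes: int = 5
) -> np.ndarray:
    """Equal-sized expression classes for stratified gene permutation.

    Genes are ranked by mean expression over all samples (ties broken by
    gene id for determinism) and split into ``n_classes`` contiguous blocks.
    Returns an integer class label per gene, aligned with ``genes``.
    """
    mean_expr = ds.values.loc[genes].mean(axis=1)
    order = np.lexsort((np.array(genes), mean_expr.to_numpy()))
    n = len(genes)
    n_classes = max(1, min(n_classes, n // 2 if n >= 4 else 1))
    labels = np.empty(n, dtype=int)
    # contiguous equal-sized blocks over the expression ranking
    edges = np.linspace(0, n, n_classes + 1).round().astype(int)
    for c in range(n_classes):
        labels[order[edges[c]:edges[c + 1]]] = c
    if n_classes > 1:
        sizes = np.bincount(labels)
        if sizes.min() < 2:
            logger.warning("expression class with < 2 genes; reduce n_classes")
    return labels


def permuted_lfc_matrix(
    lfc: np.ndarray, classes: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n_genes) matrix of lfc vectors permuted within expression class."""
    n = lfc.size
    out = np.empty((n_perm, n))
    for c in np.unique(classes):
        idx = np.flatnonzero(classes == c)
        sub = lfc[idx]
        for i in range(n_perm):
            out[i, idx] = rng.permutation(sub)
    return out


def null_curves_from_perms(
    perm_lfc: np.ndarray, gmap: DomainGeneMap, gene_index: dict[str, int]
) -> np.ndarray:
    """Ranked cumulative-sum curve of every permutation's FCC vector."""
    n_perm = perm_lfc.shape[0]
    dom_ids = gmap.domain_ids()
    fccs = np.empty((n_perm, len(dom_ids)))
    for j, d in enumerate(dom_ids):
        idx = np.array([gene_index[g] for g in gmap[d]])
        fccs[:, j] = fcc_scores_matrix(perm_lfc[:, idx])
    ranked = np.sort(fccs, axis=1)[:, ::-1]
    return np.cumsum(ranked, axis=1)


def permutation_null_curve(
    ds: ExpressionDataset,
    gmap: DomainGeneMap,
    lfc: pd.Series,
    n_perm: int = 10_000,
    n_classes: int = 5,
    quantile_level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null cumulative-sum curve from expression-stratified gene permutations.

    For each permutation, gene-to-domain assignments are shuffled within
    expression classes, FCC is recomputed per domain, and the ranked
    cumulative sum taken; the returned curve is the pointwise
    ``quantile_level`` percentile over permutations.
    """
    genes = gmap.all_genes()
    classes = expression_classes(ds, genes, n_classes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = permuted_lfc_matrix(lfc.loc[genes].to_numpy(), classes, n_perm, rng)
    gene_index = {g: i for i, g in enumerate(genes)}
    curves = null_curves_from_perms(perm, gmap, gene_index)
    if n_perm == 1:
        return curves[0]
    return np.quantile(curves, quantile_level, axis=0)


def auc_ratio(observed_curve: np.ndarray, null_curve: np.ndarray) -> float:
    """Ratio of trapezoidal areas under the observed and null curves.

    Curves are indexed by rank 1..D on a unit-spaced grid.
    """
    obs = np.asarray(observed_curve, dtype=float)
    nul = np.asarray(null_curve, dtype=float)
    if obs.shape != nul.shape or obs.size < 2:
        raise ValueError("curves must share a length >= 2")
    a_obs = np.trapezoid(obs)
    a_nul = np.trapezoid(nul)
    if a_nul <= 0:
        raise ValueError("degenerate null curve: AUC <= 0")
    return float(a_obs / a_nul)


def fully_concordant_summary(
    fcc_by_domain: pd.Series, gmap: DomainGeneMap
) -> dict[str, float]:
    """Fraction of fully concordant domains (FCC = 1), and among those the
    fraction composed of exactly 3 genes (the smallest testable size)."""
    is_full = fcc_by_domain == 1.0
    frac = float(is_full.mean()) if len(fcc_by_domain) else 0.0
    if is_full.sum() == 0:
        return {"frac_fcc1": frac, "frac_fcc1_of_size3": float("nan")}
    counts = gmap.gene_counts()
    size3 = np.mean([counts[d] == 3 for d in fcc_by_domain.index[is_full]])
    return {"frac_fcc1": frac, "frac_fcc1_of_size3": float(size3)}


@dataclass
class FCCResult:
    """Genome-wide FCC analysis bundle."""

    fcc: pd.Series
    observed_curve: np.ndarray
    null_curve: np.ndarray
    auc_ratio: float
    summary: dict[str, float]

    def table(self, gmap: DomainGeneMap) -> pd.DataFrame:
        counts = gmap.gene_counts()
        df = pd.DataFrame({"fcc": self.fcc})
        df["n_genes"] = [counts[d] for d in df.index]
        df["rank"] = df["fcc"].rank(ascending=False, method="first").astype(int)
        return df.sort_values("rank")


def run_fcc(
    ds: ExpressionDataset,
    gmap: DomainGeneMap,
    lfc: pd.Series,
    n_perm: int = 10_000,
    n_classes: int = 5,
    quantile_level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> FCCResult:
    """Full genome-wide concordance analysis: FCC per domain, observed and
    null ranked cumulative-sum curves, AUC ratio and concordance summary."""
    fcc = domain_fcc(lfc, gmap)
    observed = ranked_cumsum(fcc.to_numpy())
    null = permutation_null_curve(
        ds, gmap, lfc, n_perm=n_perm, n_classes=n_classes,
        quantile_level=quantile_level, seed=seed,
    )
    return FCCResult(
        fcc=fcc,
        observed_curve=observed,
        null_curve=null,
        auc_ratio=auc_ratio(observed, null),
        summary=fully_concordant_summary(fcc, gmap),
    )
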