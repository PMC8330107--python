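"""Genomic data model: chromatin domains, genes, expression, and pre-processing.

Coordinates are 0-based half-open throughout (BED native). GFF3/GTF input
(1-based inclusive) is converted on read. The transcription start site (TSS)
of a minus-strand gene is ``end - 1`` in these coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Input fails a structural invariant (overlap, duplicate id, ...)."""


@dataclass(frozen=True, order=True)
class GenomicDomain:
    """A chromatin domain interval on one chromosome.

    The unit of every domain-level statistic. Domains on one chromosome must
    be non-overlapping; ``domain_id`` is unique within a partition.
    """

    chrom: str
    start: int
    end: int
    domain_id: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"domain {self.domain_id or '<anon>'}: start {self.start} >= end {self.end}"
            )

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene with coordinates and strand; carries the TSS used for assignment."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start >= self.end:
            raise ValidationError(f"gene {self.gene_id}: start >= end")

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end (3' end): ``end - 1`` on +, ``start`` on -."""
        return self.end - 1 if self.strand == "+" else self.start


class DomainGeneMap:
    """Ordered mapping domain_id -> gene_ids (by TSS), plus unassigned genes."""

    def __init__(
        self,
        assignments: Mapping[str, Sequence[str]],
        domains: Sequence[GenomicDomain],
        unassigned: Sequence[str] = (),
    ) -> None:
        self._map = {d: list(gs) for d, gs in assignments.items()}
        self.domains = {d.domain_id: d for d in domains}
        self.unassigned = list(unassigned)
        seen: set[str] = set()
        for d, gs in self._map.items():
            if d not in self.domains:
                raise ValidationError(f"assignment references unknown domain {d}")
            for g in gs:
                if g in seen:
                    raise ValidationError(f"gene {g} assigned to more than one domain")
                seen.add(g)

    def __getitem__(self, domain_id: str) -> list[str]:
        return self._map[domain_id]

    def __contains__(self, domain_id: str) -> bool:
        return domain_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self):
        return iter(self._map)

    def items(self):
        return self._map.items()

    def domain_ids(self) -> list[str]:
        return list(self._map)

    def gene_counts(self) -> dict[str, int]:
        return {d: len(g) for d, g in self._map.items()}

    def all_genes(self) -> list[str]:
        return [g for gs in self._map.values() for g in gs]

    def subset(self, domain_ids: Iterable[str]) -> "DomainGeneMap":
        keep = set(domain_ids)
        dropped_genes = [g for d, gs in self._map.items() if d not in keep for g in gs]
        return DomainGeneMap(
            {d: gs for d, gs in self._map.items() if d in keep},
            [dom for dom in self.domains.values() if dom.domain_id in keep],
            unassigned=self.unassigned + dropped_genes,
        )


class ExpressionDataset:
    """A genes x samples expression matrix with a two-level condition labeling.

    Parameters
    ----------
    values
        DataFrame indexed by gene_id with sample_id columns; finite, >= 0.
    condition
        Mapping sample_id -> condition label; exactly two labels, each with
        at least two samples. ``conditions`` preserves first-appearance order,
        which fixes the fold-change sign convention (condition 2 over 1).
    """

    def __init__(self, values: pd.DataFrame, condition: Mapping[str, str]) -> None:
        if values.index.has_duplicates:
            raise ValidationError("duplicated gene_ids in expression matrix")
        if values.columns.has_duplicates:
            raise ValidationError("duplicated sample_ids in expression matrix")
        missing = [s for s in values.columns if s not in condition]
        if missing:
            raise ValidationError(f"samples without condition label: {missing[:5]}")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if np.any(arr < 0):
            raise ValidationError("expression values must be >= 0")
        cond = {s: condition[s] for s in values.columns}
        levels: list[str] = []
        for s in values.columns:
            if cond[s] not in levels:
                levels.append(cond[s])
        if len(levels) != 2:
            raise ValidationError(f"expected exactly 2 conditions, got {levels}")
        counts = pd.Series(list(cond.values())).value_counts()
        if counts.min() < 2:
            raise ValidationError("both conditions need >= 2 samples")
        self.values = values
        self.condition = cond
        self.conditions: tuple[str, str] = (levels[0], levels[1])

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, level: str) -> list[str]:
        return [s for s in self.samples if self.condition[s] == level]

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        return ExpressionDataset(values, self.condition)

    def swap_conditions(self) -> "ExpressionDataset":
        """Same data with the condition order (hence fold-change sign) flipped."""
        ds = ExpressionDataset(self.values, self.condition)
        ds.conditions = (self.conditions[1], self.conditions[0])
        return ds


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_domains(path) -> list[GenomicDomain]:
    """Read a 3+ column BED of chromatin domains.

    Domains are sorted per chromosome and validated to be non-overlapping.
    A missing 4th column yields auto ids ``D<chrom>.<i>``.
    """
    domains: list[GenomicDomain] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 and parts[3] not in {"", "."} else ""
            domains.append(GenomicDomain(parts[0], start, end, name))
    return _finalize_domains(domains)


def _finalize_domains(domains: Sequence[GenomicDomain]) -> list[GenomicDomain]:
    """Sort, auto-name, and reject overlaps per chromosome."""
    out: list[GenomicDomain] = []
    by_chrom: dict[str, list[GenomicDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    ids_seen: set[str] = set()
    for chrom in sorted(by_chrom):
        ds = sorted(by_chrom[chrom], key=lambda d: (d.start, d.end))
        for i, d in enumerate(ds):
            if i and d.start < ds[i - 1].end:
                raise ValidationError(
                    f"overlapping domains on {chrom}: "
                    f"[{ds[i-1].start},{ds[i-1].end}) and [{d.start},{d.end})"
                )
            did = d.domain_id or f"D{chrom}.{i}"
            if did in ids_seen:
                raise ValidationError(f"duplicate domain_id {did}")
            ids_seen.add(did)
            out.append(GenomicDomain(d.chrom, d.start, d.end, did))
    return out


def read_genes(path) -> list[GeneRecord]:
    """Read gene annotations from GFF3/GTF or a 5-column TSV.

    The TSV form has columns gene_id, chrom, strand, start, end with a header,
    0-based half-open coordinates. GFF3/GTF (detected by extension or a 9-column
    body with a ``gene`` feature) is 1-based inclusive and converted on read.
    """
    p = str(path)
    if p.endswith((".gff", ".gff3", ".gtf")):
        return _read_genes_gff(path)
    return _read_genes_tsv(path)


def _read_genes_tsv(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "strand", "start", "end"}
    if not required.issubset(df.columns):
        raise ValidationError(f"gene TSV needs columns {sorted(required)}")
    genes = [
        GeneRecord(r.gene_id, r.chrom, r.strand, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
    _check_unique_gene_ids(genes)
    return genes


def _read_genes_gff(path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValidationError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts
            if feature != "gene":
                continue
            if strand not in {"+", "-"}:
                raise ValidationError(f"{path}:{lineno}: missing or invalid strand")
            gid = _gff_attr(attrs, ("ID", "gene_id"))
            if gid is None:
                raise ValidationError(f"{path}:{lineno}: no gene id in attributes")
            # GFF is 1-based inclusive -> 0-based half-open
            genes.append(GeneRecord(gid, chrom, strand, int(start) - 1, int(end)))
    _check_unique_gene_ids(genes)
    return genes


def _gff_attr(attrs: str, keys: tuple[str, ...]) -> str | None:
    for token in attrs.replace("; ", ";").split(";"):
        token = token.strip()
        if not token:
            continue
        if "=" in token:  # GFF3
            k, v = token.split("=", 1)
        else:  # GTF: key "value"
            bits = token.split(None, 1)
            if len(bits) != 2:
                continue
            k, v = bits[0], bits[1].strip('"')
        if k in keys:
            return v.strip('"')
    return None


def _check_unique_gene_ids(genes: Sequence[GeneRecord]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)


def read_expression(path) -> pd.DataFrame:
    """Read a TSV expression matrix: header of sample ids, first column gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def read_conditions(path) -> dict[str, str]:
    """Read a 2-column TSV sample_id -> condition (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("condition file needs 2 columns: sample_id, condition")
    first = df.iloc[0]
    if first.iloc[0].lower() in {"sample", "sample_id"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_dataset(expr_path, cond_path) -> ExpressionDataset:
    return ExpressionDataset(read_expression(expr_path), read_conditions(cond_path))


# ---------------------------------------------------------------------------
# Gene-to-domain assignment and filters
# ---------------------------------------------------------------------------

def assign_genes_to_domains(
    genes: Sequence[GeneRecord], domains: Sequence[GenomicDomain]
) -> DomainGeneMap:
    """Assign each gene to the domain containing its TSS.

    If no domain contains the TSS but one contains the gene's 3' end, the gene
    is assigned to that domain (rescues genes whose promoter falls in a gap
    between domains). Genes matching neither rule are recorded as unassigned.
    """
    domains = _finalize_domains(domains)
    by_chrom: dict[str, list[GenomicDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    starts = {c: np.array([d.start for d in ds]) for c, ds in by_chrom.items()}
    ends = {c: np.array([d.end for d in ds]) for c, ds in by_chrom.items()}

    def locate(chrom: str, pos: int) -> GenomicDomain | None:
        if chrom not in by_chrom:
            return None
        i = int(np.searchsorted(starts[chrom], pos, side="right")) - 1
        if i >= 0 and pos < ends[chrom][i]:
            return by_chrom[chrom][i]
        return None

    assigned: dict[str, list[tuple[int, str]]] = {d.domain_id: [] for d in domains}
    unassigned: list[str] = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        dom = locate(g.chrom, g.tss) or locate(g.chrom, g.end - 1)
        if dom is None:
            unassigned.append(g.gene_id)
        else:
            assigned[dom.domain_id].append((g.tss, g.gene_id))
    ordered = {d: [gid for _, gid in sorted(pairs)] for d, pairs in assigned.items()}
    return DomainGeneMap(ordered, domains, unassigned=unassigned)


def filter_domains(
    gmap: DomainGeneMap, min_genes: int = 3, max_genes_quantile: float = 0.99
) -> DomainGeneMap:
    """Keep domains with ``min_genes <= n <= Q(max_genes_quantile)`` genes.

    The gene-count cap is the dataset-specific nearest-rank quantile of the
    pre-filter gene-count distribution (the cap is always an observed count,
    so the rule never drops the maximum of a small unexceptional dataset).
    """
    counts = gmap.gene_counts()
    if not counts:
        raise ValidationError("no testable domains: empty map")
    cap = float(np.quantile(list(counts.values()), max_genes_quantile, method="nearest"))
    keep = [d for d, n in counts.items() if min_genes <= n <= cap]
    if not keep:
        raise ValidationError("no testable domains after size filtering")
    return gmap.subset(keep)


def filter_genes_by_coverage(
    ds: ExpressionDataset, min_reads: float = 5, min_sample_frac: float = 0.80
) -> ExpressionDataset:
    """Keep genes with >= ``min_reads`` in at least ``min_sample_frac`` of samples."""
    frac = (ds.values >= min_reads).mean(axis=1)
    return ds.with_values(ds.values.loc[frac >= min_sample_frac])


def upper_quartile_scale(ds: ExpressionDataset, target: float = 1000.0) -> ExpressionDataset:
    """Scale each sample by its 75th percentile of nonzero values, times ``target``."""
    vals = ds.values.to_numpy(dtype=float)
    uq = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        col = vals[:, j]
        nz = col[col > 0]
        uq[j] = np.percentile(nz, 75) if nz.size else 1.0
    scaled = vals / uq[None, :] * target
    return ds.with_values(pd.DataFrame(scaled, index=ds.values.index, columns=ds.values.columns))


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Rank-mean quantile normalization: every column gets the same distribution.

    The reference distribution is the per-rank mean over columns of the sorted
    values. Ties within a column receive the mean of their tied reference
    values (average-rank convention).
    """
    x = ds.values.to_numpy(dtype=float)
    return ds.with_values(
        pd.DataFrame(quantile_normalize_array(x), index=ds.values.index, columns=ds.values.columns)
    )


def quantile_normalize_array(x: np.ndarray) -> np.ndarray:
    n, m = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(m):
        col = x[:, j]
        # average rank (0-based) of each entry within its column
        ranks = np.empty(n)
        ranks[order[:, j]] = np.arange(n)
        # ties: replace rank by the mean rank of the tied group, then
        # interpolate the reference at that (possibly fractional) rank
        vals, inv = np.unique(col, return_inverse=True)
        mean_rank = np.zeros(len(vals))
        np.add.at(mean_rank, inv, ranks)
        cnt = np.bincount(inv)
        mean_rank /= cnt
        # fractional rank -> mean of the reference values the tied group spans
        cum = np.concatenate([[0.0], np.cumsum(ref)])
        lo = np.concatenate([[0], np.cumsum(cnt)])[:-1]
        grp_mean_ref = (cum[lo + cnt] - cum[lo]) / cnt
        out[:, j] = grp_mean_ref[inv]
    return out
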