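"""Differential interactome test on per-pixel contact-significance matrices.

Inputs are symmetric matrices of interaction strength S = -log10(p) of
contact significance per pixel (bin pair), one per condition, produced
upstream by a significance caller. The test computes the per-pixel
difference dS = S1 - S2, builds an empirical background from all pixels
within a genomic-separation window (default 2 Mb), and assigns each pixel a
two-tailed empirical p-value and a direction (+1: stronger in condition 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class InteractionStrengthMatrix:
    """Symmetric per-pixel interaction strength for one chromosome.

    ``S[i, j] = -log10(p)`` of the contact between bins i and j; missing
    pixels are NaN. ``bin_size`` in bp.
    """

    chrom: str
    bin_size: int
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError("S must be square")
        present = np.isfinite(self.S)
        if not np.array_equal(present, present.T) or not np.allclose(
            self.S[present & present.T], self.S.T[present & present.T]
        ):
            raise ValueError("S must be symmetric where present")
        if np.any(self.S[present] < 0):
            raise ValueError("interaction strengths must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.S.shape[0]

    @classmethod
    def from_triplets(
        cls, chrom: str, bin_size: int, triplets: pd.DataFrame, n_bins: int | None = None
    ) -> "InteractionStrengthMatrix":
        """Build from a (bin_i, bin_j, S) coordinate table; symmetrized."""
        i = triplets.iloc[:, 0].to_numpy(dtype=int)
        j = triplets.iloc[:, 1].to_numpy(dtype=int)
        s = triplets.iloc[:, 2].to_numpy(dtype=float)
        n = n_bins or int(max(i.max(), j.max())) + 1
        S = np.full((n, n), np.nan)
        S[i, j] = s
        S[j, i] = s
        return cls(chrom, bin_size, S)


def read_interaction_matrix(path, chrom: str, bin_size: int) -> InteractionStrengthMatrix:
    """Read a dense TSV matrix or a 3-column (bin_i, bin_j, S) triplet TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 3 and df.shape[0] != 3:
        return InteractionStrengthMatrix.from_triplets(chrom, bin_size, df)
    return InteractionStrengthMatrix(chrom, bin_size, df.to_numpy(dtype=float))


def delta_s(
    m1: InteractionStrengthMatrix, m2: InteractionStrengthMatrix
) -> InteractionStrengthMatrix:
    """Elementwise difference of interaction strength, S1 - S2.

    Defined only on pixels present in both inputs; NaN elsewhere. The result
    reuses the container but may be negative (it is a difference, not a
    strength), so validation is bypassed.
    """
    if m1.chrom != m2.chrom or m1.bin_size != m2.bin_size or m1.S.shape != m2.S.shape:
        raise ValueError("matrices must match in chromosome, bin size and shape")
    out = InteractionStrengthMatrix.__new__(InteractionStrengthMatrix)
    out.chrom = m1.chrom
    out.bin_size = m1.bin_size
    out.S = m1.S - m2.S
    return out


def background_distribution(
    delta_matrices: list[InteractionStrengthMatrix], window: int = 2_000_000
) -> np.ndarray:
    """Pool dS values of all pixels with genomic separation <= ``window``.

    Off-diagonal pixels up to ``window // bin_size`` bins from the diagonal
    (upper triangle including the diagonal) across all chromosomes.
    """
    pool: list[np.ndarray] = []
    for dm in delta_matrices:
        if window < dm.bin_size:
            raise ValueError("window smaller than bin size")
        max_off = window // dm.bin_size
        n = dm.n_bins
        i, j = np.triu_indices(n)
        sel = (j - i) <= max_off
        vals = dm.S[i[sel], j[sel]]
        pool.append(vals[np.isfinite(vals)])
    out = np.concatenate(pool) if pool else np.array([])
    if out.size == 0:
        raise ValueError("empty background pool")
    return out


def empirical_two_tailed_p(delta: float, background: np.ndarray) -> tuple[float, int]:
    """Two-tailed empirical p of a dS value against the pooled background.

    ``p = (1 + #{b: |b| >= |delta|}) / (1 + |background|)``; direction is
    sign(delta): +1 when the contact is stronger in condition 1.
    """
    bg = np.abs(np.asarray(background, dtype=float))
    if bg.size == 0:
        raise ValueError("empty background")
    hits = int(np.sum(bg >= abs(delta)))
    return (1 + hits) / (1 + bg.size), int(np.sign(delta))


def pixel_table(
    dm: InteractionStrengthMatrix, background: np.ndarray
) -> pd.DataFrame:
    """Per-pixel dS, empirical p and direction for the upper triangle."""
    sorted_abs = np.sort(np.abs(background))
    n_bg = sorted_abs.size
    i, j = np.triu_indices(dm.n_bins)
    d = dm.S[i, j]
    ok = np.isfinite(d)
    i, j, d = i[ok], j[ok], d[ok]
    ge = n_bg - np.searchsorted(sorted_abs, np.abs(d), side="left")
    p = (1 + ge) / (1 + n_bg)
    return pd.DataFrame(
        {
            "chrom": dm.chrom,
            "bin_i": i,
            "bin_j": j,
            "delta_s": d,
            "p": p,
            "direction": np.sign(d).astype(int),
        }
    )


def domain_interactome_summary(
    activity_table: pd.DataFrame,
    pixels: pd.DataFrame,
    bin_size: int,
    significant_only: bool = True,
) -> dict[str, np.ndarray]:
    """Signed -log10(p) of intra-domain pixels per differentially active domain.

    The sign is the pixel's direction: positive for contacts stronger in
    condition 1. Domains with no intra-domain pixels yield an empty array;
    domains outside the matrix extent are skipped.
    """
    rows = activity_table[activity_table["significant"]] if significant_only else activity_table
    out: dict[str, np.ndarray] = {}
    for domain_id, row in rows.iterrows():
        sub = pixels[pixels["chrom"] == row["chrom"]]
        if sub.empty:
            continue
        b0, b1 = row["start"] // bin_size, (row["end"] - 1) // bin_size
        sel = (sub["bin_i"] >= b0) & (sub["bin_j"] <= b1)
        picked = sub[sel]
        signed = picked["direction"].to_numpy() * (-np.log10(picked["p"].to_numpy()))
        out[str(domain_id)] = signed
    return out
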