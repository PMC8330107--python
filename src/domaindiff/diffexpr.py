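"""Gene-level differential expression between two conditions.

Implements an empirical-Bayes moderated two-sample t-statistic: gene-wise
residual variances are shrunk toward a pooled prior whose scale and degrees
of freedom are estimated by matching moments of the log sample variances to
a scaled F distribution. A plain Welch t is available as a fallback mode.

Fold-change sign convention: condition 2 over condition 1, where the order
of the two conditions is the order of first appearance in the sample
annotation (``ExpressionDataset.conditions``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .genome import ExpressionDataset


@dataclass(frozen=True)
class GeneDEResult:
    gene_id: str
    lfc: float
    t_stat: float
    p: float
    p_adj: float
    rank: int


def compute_lfc(ds: ExpressionDataset, pseudocount: float = 1.0) -> pd.Series:
    """Per-gene log2 fold-change of condition-2 mean over condition-1 mean.

    ``lfc(g) = log2((mean_2 + pseudocount) / (mean_1 + pseudocount))`` on
    whatever scale ``ds`` carries; apply normalization upstream.
    """
    c1, c2 = ds.conditions
    s1, s2 = ds.samples_of(c1), ds.samples_of(c2)
    if not s1 or not s2:
        raise ValueError("both conditions need at least one sample")
    m1 = ds.values[s1].mean(axis=1)
    m2 = ds.values[s2].mean(axis=1)
    return np.log2((m2 + pseudocount) / (m1 + pseudocount))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``p_adj[i] = min_{j: p_j >= p_i} (n * p_j / rank_j)`` clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match ``s2 ~ s0^2 F(df, d0)`` on the log scale.

    Returns (d0, s0sq); d0 = inf when the observed spread of log variances is
    no larger than expected from the chi-square sampling noise alone.
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    n = len(z)
    evar = np.var(e, ddof=1) * (n - 1) / n - special.polygamma(1, df / 2)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    # invert trigamma(d0/2) = evar by Newton on x = d0/2 (limma's trigammaInverse)
    x = 0.5 + 1.0 / evar
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / evar) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-8 * x:
            break
    d0 = 2 * x
    s0sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return float(d0), s0sq


def moderated_de_test(
    ds: ExpressionDataset, moderated: bool = True, prior_df: float | None = None
) -> pd.DataFrame:
    """Two-group differential expression with variance moderation.

    Returns a DataFrame indexed by gene with columns lfc, t, p, p_adj, rank.
    ``moderated=False`` gives the ordinary pooled-variance t-test.
    ``prior_df`` overrides the estimated prior degrees of freedom (0 disables
    shrinkage; inf fully pools).
    """
    c1, c2 = ds.conditions
    s1, s2 = ds.samples_of(c1), ds.samples_of(c2)
    n1, n2 = len(s1), len(s2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per condition")
    df_resid = n1 + n2 - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    x1 = ds.values[s1].to_numpy(dtype=float)
    x2 = ds.values[s2].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2g = ss / df_resid
    lfc = m2 - m1  # values assumed already on a log2 scale
    se_unscaled = np.sqrt(1.0 / n1 + 1.0 / n2)

    if moderated:
        if prior_df is None:
            d0, s0sq = _fit_f_dist(s2g, df_resid)
        elif prior_df == 0:
            d0, s0sq = 0.0, 0.0
        else:
            d0, s0sq = float(prior_df), float(np.median(s2g))
        if np.isinf(d0):
            s2_post = np.full_like(s2g, s0sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0sq + df_resid * s2g) / (d0 + df_resid)
            df_total = df_resid + d0
    else:
        s2_post, df_total = s2g, float(df_resid)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (np.sqrt(s2_post) * se_unscaled)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {"lfc": lfc, "t": t, "p": p, "p_adj": bh_adjust(p)}, index=ds.values.index
    )
    out["rank"] = out["p"].rank(method="first").astype(int)
    return out


def de_results(table: pd.DataFrame) -> list[GeneDEResult]:
    """Convert a result table to typed records."""
    return [
        GeneDEResult(g, float(r.lfc), float(r.t), float(r.p), float(r.p_adj), int(r.rank))
        for g, r in table.iterrows()
    ]
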