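"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, clipped at 1).

    NaN inputs propagate to NaN outputs and are excluded from the adjustment.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(ranked, 0.0, 1.0)
    out[ok] = adj
    return out


def rank01(x: np.ndarray) -> np.ndarray:
    """Average ranks scaled to [0, 1]; a single value maps to 0.5."""
    x = np.asarray(x, dtype=float)
    r = stats.rankdata(x, method="average")
    if x.size == 1:
        return np.array([0.5])
    return (r - 1.0) / (x.size - 1.0)


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman correlation via the t approximation (n-2 df)."""
    if n < 3 or not np.isfinite(rho):
        return np.nan
    r = min(max(rho, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def columnwise_spearman(mat: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix between the columns of ``mat``.

    Rank-transforms each column (average ties) and takes Pearson correlations
    of the ranks via one matrix product; exact equality with the pairwise
    definition.
    """
    ranks = np.apply_along_axis(stats.rankdata, 0, np.asarray(mat, dtype=float))
    ranks -= ranks.mean(axis=0, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=0))
    norm[norm == 0] = np.nan
    ranks /= norm
    c = ranks.T @ ranks
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)
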