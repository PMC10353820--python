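"""Consensus variance/mean gene ranks via PC1 projection.

A gene's consensus score is the projection of its per-study rank profile onto
the leading eigenvector of the study-by-study Spearman correlation matrix.
Genes present in at least half the studies enter the rank; missing cells are
filled by iterative low-rank (PCA) imputation on the rank-transformed matrix.
Tissue-level ranks use complete cases within the tissue and need no
imputation; a single-study tissue falls back to that study's own SD rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import columnwise_spearman
from .crossstudy import SDMatrix

logger = logging.getLogger(__name__)


@dataclass
class VarianceRank:
    """Ordered gene list with PC1 scores (rank 1 = lowest variance/mean)."""

    genes: pd.Index
    pc1_score: pd.Series
    rank: pd.Series  # permutation of 1..M
    presence_fraction: pd.Series
    kind: str  # "variance" or "mean"
    scope: str  # "across-study" or "tissue:<name>"
    pc_variance_explained: np.ndarray

    def __post_init__(self) -> None:
        r = np.sort(self.rank.to_numpy())
        if not np.array_equal(r, np.arange(1, len(r) + 1)):
            raise ValueError("rank must be a permutation of 1..M")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def tail_sets(self, fraction: float = 0.05) -> tuple[set[str], set[str]]:
        """(high-variance, low-variance) tail gene sets of size floor(f*M)."""
        k = int(np.floor(fraction * self.n_genes))
        order = self.rank.sort_values()
        return set(order.index[-k:]) if k else set(), set(order.index[:k]) if k else set()


def impute_missing_ranks(
    matrix: pd.DataFrame,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Iterative low-rank imputation; observed cells are never altered.

    Missing cells start at column means, then alternate truncated-SVD
    reconstruction with missing-cell updates until the largest absolute change
    is below ``tol`` or ``max_iter`` is reached (warning, best iterate kept).
    """
    mask = matrix.isna().to_numpy()
    if mask.all(axis=1).any():
        raise ValueError("a gene row is entirely missing")
    if not mask.any():
        return matrix.copy()
    if n_components >= min(matrix.shape):
        raise ValueError("n_components must be < min(matrix dimensions)")
    x = matrix.to_numpy(dtype=float).copy()
    col_means = np.nanmean(x, axis=0)
    x[mask] = np.take(col_means, np.where(mask)[1])
    for _ in range(max_iter):
        center = x.mean(axis=0)
        u, s, vt = np.linalg.svd(x - center[None, :], full_matrices=False)
        recon = (u[:, :n_components] * s[None, :n_components]) @ vt[:n_components] + center[None, :]
        delta = np.max(np.abs(recon[mask] - x[mask]))
        x[mask] = recon[mask]
        if delta < tol:
            break
    else:
        warnings.warn("PCA imputation did not converge; returning best iterate")
    return pd.DataFrame(x, index=matrix.index, columns=matrix.columns)


def _rank01_with_na(col: np.ndarray) -> np.ndarray:
    """Average-tie ranks of a column's observed values, scaled to [0, 1]."""
    out = np.full(col.shape, np.nan)
    ok = np.isfinite(col)
    m = ok.sum()
    if m == 0:
        return out
    r = stats.rankdata(col[ok], method="average")
    out[ok] = (r - 1.0) / (m - 1.0) if m > 1 else 0.5
    return out


def _project_pc1(rank_mat: pd.DataFrame, kind: str, scope: str, presence: pd.Series) -> VarianceRank:
    """Score genes on the leading eigenvector of the study-rank correlation."""
    arr = rank_mat.to_numpy(dtype=float)
    corr = columnwise_spearman(arr)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if len(eigval) > 1 and abs(eigval[0] - eigval[1]) < 1e-12:
        logger.warning("leading eigenvalue tied; breaking deterministically by study order")
    v1 = eigvec[:, 0]
    centered = arr - arr.mean(axis=0, keepdims=True)
    score = centered @ v1
    # orient PC1 so higher score = higher per-study rank (higher SD/mean)
    mean_rank = arr.mean(axis=1)
    if np.corrcoef(score, mean_rank)[0, 1] < 0:
        score = -score
    score_s = pd.Series(score, index=rank_mat.index)
    rank = score_s.rank(method="first").astype(int)
    return VarianceRank(
        genes=rank_mat.index,
        pc1_score=score_s,
        rank=rank,
        presence_fraction=presence,
        kind=kind,
        scope=scope,
        pc_variance_explained=eigval / eigval.sum(),
    )


def compute_rank(
    sd: SDMatrix,
    kind: str = "variance",
    min_presence: float = 0.5,
    n_components: int = 2,
) -> VarianceRank:
    """Across-study consensus rank of genes by SD (or mean) PC1 projection.

    Keeps genes present in >= ``min_presence`` of studies, rank-transforms each
    study column to [0, 1], imputes missing cells, and projects each gene's
    centered rank profile onto the leading eigenvector of the study-by-study
    Spearman correlation matrix. Rank M = highest variance (or mean).
    """
    values = sd.sd if kind == "variance" else sd.mean
    if values.shape[1] < 2:
        raise ValueError("need at least 2 studies")
    presence = values.notna().mean(axis=1)
    keep = presence >= min_presence
    if keep.sum() < 3:
        raise ValueError("fewer than 3 genes pass the presence threshold")
    vals = values.loc[keep]
    ranked = pd.DataFrame(
        np.apply_along_axis(_rank01_with_na, 0, vals.to_numpy(dtype=float)),
        index=vals.index,
        columns=vals.columns,
    )
    n_comp = min(n_components, min(ranked.shape) - 1)
    complete = impute_missing_ranks(ranked, n_components=n_comp)
    return _project_pc1(complete, kind, "across-study", presence.loc[keep])


def compute_mean_rank(sd: SDMatrix, min_presence: float = 0.5) -> VarianceRank:
    """Across-study mean-expression rank: identical machinery, mean matrix."""
    return compute_rank(sd, kind="mean", min_presence=min_presence)


def compute_tissue_ranks(sd: SDMatrix, kind: str = "variance") -> dict[str, VarianceRank]:
    """Per-tissue ranks over the tissue's complete-case genes (no imputation).

    A tissue represented by a single study uses that study's own rank.
    """
    values = sd.sd if kind == "variance" else sd.mean
    out: dict[str, VarianceRank] = {}
    for tissue in sd.tissues.unique():
        studies = sd.tissues.index[sd.tissues == tissue]
        if len(studies) == 0:
            raise ValueError(f"tissue {tissue!r} has no studies")
        sub = values.loc[:, studies].dropna(axis=0)
        presence = pd.Series(1.0, index=sub.index)
        scope = f"tissue:{tissue}"
        if len(studies) == 1:
            score = sub.iloc[:, 0]
            rank = score.rank(method="first").astype(int)
            out[tissue] = VarianceRank(
                genes=sub.index,
                pc1_score=score,
                rank=rank,
                presence_fraction=presence,
                kind=kind,
                scope=scope,
                pc_variance_explained=np.array([1.0]),
            )
            continue
        ranked = pd.DataFrame(
            np.apply_along_axis(_rank01_with_na, 0, sub.to_numpy(dtype=float)),
            index=sub.index,
            columns=sub.columns,
        )
        out[tissue] = _project_pc1(ranked, kind, scope, presence)
    return out
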