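"""Gene-by-study SD matrix, study-level Spearman correlations, and PCoA."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import columnwise_spearman
from .preprocess import GeneSummary

logger = logging.getLogger(__name__)


@dataclass
class SDMatrix:
    """Gene x study matrices of residual SDs and means, with missingness.

    Missing cells (NaN) mark genes that failed a study's expression filter.
    """

    sd: pd.DataFrame  # genes x studies, NaN = missing
    mean: pd.DataFrame  # identical shape
    tissues: pd.Series  # per-study tissue label
    sources: pd.Series  # per-study source label

    def __post_init__(self) -> None:
        if self.sd.isna().all(axis=1).any():
            raise ValueError("SDMatrix contains an entirely-missing gene row")
        vals = self.sd.to_numpy()
        if np.nanmin(vals) < 0:
            raise ValueError("SD values must be >= 0")

    @property
    def presence(self) -> pd.DataFrame:
        return self.sd.notna()


@dataclass
class StudyCorrelation:
    """Study x study Spearman correlation matrix over complete-case genes."""

    matrix: pd.DataFrame
    tissues: pd.Series
    sources: pd.Series
    n_common_genes: int

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(m)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")


def build_sd_matrix(summaries: list[GeneSummary]) -> SDMatrix:
    """Union-of-genes SD (and mean) matrix across studies; NaN where absent."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 studies")
    ids = [s.study_id for s in summaries]
    if len(set(ids)) != len(ids):
        raise ValueError("study IDs must be unique")
    for s in summaries:
        if s.sd.index.has_duplicates:
            raise ValueError(f"{s.study_id}: duplicated gene IDs")
    sd = pd.concat([s.sd.rename(s.study_id) for s in summaries], axis=1)
    mean = pd.concat([s.mean.rename(s.study_id) for s in summaries], axis=1)
    tissues = pd.Series({s.study_id: s.tissue for s in summaries})
    sources = pd.Series({s.study_id: s.source for s in summaries})
    return SDMatrix(sd=sd, mean=mean.loc[sd.index], tissues=tissues, sources=sources)


def spearman_correlation_matrix(sd: SDMatrix, use: str = "sd") -> StudyCorrelation:
    """Spearman correlations between study columns over complete-case genes.

    Ties get average ranks; the number of tied values is logged. ``use``
    selects the SD (default) or mean matrix.
    """
    values = sd.sd if use == "sd" else sd.mean
    complete = values.dropna(axis=0)
    if complete.shape[0] < 3:
        raise ValueError(f"only {complete.shape[0]} complete-case genes; need >= 3")
    arr = complete.to_numpy(dtype=float)
    n_ties = sum(len(col) - len(np.unique(col)) for col in arr.T)
    if n_ties:
        logger.info("spearman_correlation_matrix: %d tied values across studies", n_ties)
    corr = columnwise_spearman(arr)
    return StudyCorrelation(
        matrix=pd.DataFrame(corr, index=values.columns, columns=values.columns),
        tissues=sd.tissues,
        sources=sd.sources,
        n_common_genes=complete.shape[0],
    )


def pcoa(corr: StudyCorrelation) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical MDS of the between-study distances ``d_ij = |1 - rho_ij|``.

    Double-centers the squared-distance matrix, eigendecomposes, and returns
    coordinates on the positive-eigenvalue axes (ordered by eigenvalue) plus
    the full eigenvalue vector including any negative values.
    """
    d = np.abs(1.0 - corr.matrix.to_numpy(dtype=float))
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0.0) * 1e-12
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])[None, :]
    frame = pd.DataFrame(
        coords, index=corr.matrix.index, columns=[f"axis{i+1}" for i in range(coords.shape[1])]
    )
    return frame, eigval
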