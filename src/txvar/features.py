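"""Gene-level covariates of the variance rank.

Co-expression network connectivity, genomic window metrics assigned to genes,
chromatin-state proportions of flanked gene regions, rank-based group
comparisons of those proportions, and partial Spearman correlations of
features with the variance rank controlling for the mean rank.

All interval arithmetic is 0-based half-open (BED convention); strand is
stored but ignored for overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, spearman_pvalue
from .preprocess import ExpressionMatrix
from .ranking import VarianceRank


@dataclass(frozen=True)
class GeneRegion:
    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene}: start must be < end")


def regions_from_frame(frame: pd.DataFrame) -> list[GeneRegion]:
    return [
        GeneRegion(r.gene, r.chrom, int(r.start), int(r.end), getattr(r, "strand", "+"))
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# connectivity


def _study_connectivity(
    values: pd.DataFrame, fdr: float, signed: bool
) -> pd.Series:
    n_genes, n_samples = values.shape
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if n_samples < 5:
        raise ValueError("need at least 5 samples per study")
    ranks = np.apply_along_axis(stats.rankdata, 1, values.to_numpy(dtype=float))
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    norm[norm == 0] = np.nan
    ranks /= norm[:, None]
    corr = np.clip(ranks @ ranks.T, -1.0, 1.0)

    iu = np.triu_indices(n_genes, k=1)
    rho = corr[iu]
    pvals = np.array([spearman_pvalue(r, n_samples) for r in rho])
    keep = bh_adjust(pvals) <= fdr
    adj = np.zeros_like(corr)
    vals = np.where(keep, np.abs(rho) if not signed else rho, 0.0)
    adj[iu] = vals
    adj += adj.T
    return pd.Series(adj.sum(axis=1), index=values.index)


def weighted_connectivity(
    expr_matrices: list[ExpressionMatrix], fdr: float = 0.01, signed: bool = True
) -> pd.Series:
    """Per-gene signed sum of FDR-surviving co-expression edges, averaged
    over the studies in which the gene is expressed.

    Per study the full gene-by-gene Spearman graph is trimmed at a BH FDR of
    ``fdr`` (edge p-values from the t approximation) and each gene's surviving
    edge correlations are summed. ``signed=False`` sums absolute correlations
    (sensitivity mode).
    """
    per_study = [_study_connectivity(m.values, fdr, signed) for m in expr_matrices]
    return pd.concat(per_study, axis=1).mean(axis=1)


# ---------------------------------------------------------------------------
# interval operations


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def windows_to_genes(track: pd.DataFrame, regions: list[GeneRegion]) -> pd.Series:
    """Unweighted mean of the window metric over windows overlapping each gene.

    ``track`` has columns chrom, start, end, value with non-overlapping
    windows; genes on chromosomes absent from the track, or overlapping no
    window, are missing (NaN).
    """
    if (track["end"] <= track["start"]).any():
        raise ValueError("malformed window intervals")
    by_chrom = {c: g.sort_values("start") for c, g in track.groupby("chrom")}
    out = {}
    for region in regions:
        sub = by_chrom.get(region.chrom)
        if sub is None:
            out[region.gene] = np.nan
            continue
        hit = (sub["start"].to_numpy() < region.end) & (sub["end"].to_numpy() > region.start)
        out[region.gene] = float(sub.loc[hit, "value"].mean()) if hit.any() else np.nan
    return pd.Series(out)


def chromatin_state_proportions(
    segmentation: pd.DataFrame,
    regions: list[GeneRegion],
    flank: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene proportion of the flanked region in each chromatin state.

    Regions are extended by ``flank`` bases on both sides, clipped at 0 and at
    the chromosome length when provided; the proportion is overlapped bases per
    state divided by the extended region length. A partitioning segmentation
    yields rows summing to 1.
    """
    if (segmentation["end"] <= segmentation["start"]).any():
        raise ValueError("malformed segmentation intervals")
    if segmentation["state"].isna().any():
        raise ValueError("state labels missing")
    states = sorted(segmentation["state"].unique())
    by_chrom = {c: g for c, g in segmentation.groupby("chrom")}
    rows = {}
    for region in regions:
        lo = max(region.start - flank, 0)
        hi = region.end + flank
        if chrom_lengths and region.chrom in chrom_lengths:
            hi = min(hi, chrom_lengths[region.chrom])
        length = hi - lo
        counts = dict.fromkeys(states, 0)
        sub = by_chrom.get(region.chrom)
        if sub is not None:
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            hit = (s < hi) & (e > lo)
            for st, ss, ee in zip(sub.loc[hit, "state"], s[hit], e[hit]):
                counts[st] += _overlap(lo, hi, ss, ee)
        rows[region.gene] = {st: counts[st] / length for st in states}
    return pd.DataFrame.from_dict(rows, orient="index")[states]


def compare_groups_states(
    proportions: pd.DataFrame,
    high: set[str],
    low: set[str],
    paired: bool = False,
) -> pd.DataFrame:
    """Per-state rank test of high- vs low-tail state proportions, with BH.

    Default is the unpaired Mann-Whitney rank-sum test; ``paired=True``
    switches to the Wilcoxon signed-rank test on positionally paired groups
    (kept selectable because some published analyses name the signed-rank
    test for what are unpaired gene groups). Reports per-group median and
    standard error of the mean.
    """
    hi = proportions.loc[proportions.index.intersection(sorted(high))]
    lo = proportions.loc[proportions.index.intersection(sorted(low))]
    if set(hi.index) & set(lo.index):
        raise ValueError("high and low groups must be disjoint")
    if min(len(hi), len(lo)) < 3:
        raise ValueError("minimum group size is 3")
    if paired and len(hi) != len(lo):
        raise ValueError("paired mode requires equal group sizes")
    rows = []
    for state in proportions.columns:
        a, b = hi[state].to_numpy(), lo[state].to_numpy()
        constant = a.std() == 0 and b.std() == 0 and (len(a) == 0 or len(b) == 0 or a[0] == b[0])
        if constant:
            stat, p = np.nan, 1.0
        elif paired:
            diff = a - b
            if np.all(diff == 0):
                stat, p = np.nan, 1.0
            else:
                stat, p = stats.wilcoxon(a, b)
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "state": state,
                "statistic": float(stat),
                "p": float(p),
                "median_high": float(np.median(a)),
                "median_low": float(np.median(b)),
                "sem_high": float(a.std(ddof=1) / np.sqrt(len(a))),
                "sem_low": float(b.std(ddof=1) / np.sqrt(len(b))),
                "flag": "constant" if constant else "",
            }
        )
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = bh_adjust(frame["p"].to_numpy())
    return frame


# ---------------------------------------------------------------------------
# partial correlation


def partial_spearman(
    feature: pd.Series, rank: VarianceRank, control: VarianceRank
) -> tuple[float, float]:
    """Partial Spearman correlation of a feature with the variance rank,
    controlling for the mean rank.

    All three vectors are rank-transformed over the genes where all are
    observed; the partial correlation is the Pearson correlation of the
    residuals from regressing feature ranks and variance ranks on the control
    ranks, with a t-approximation p-value at n-3 df.
    """
    common = feature.dropna().index.intersection(rank.rank.index).intersection(
        control.rank.index
    )
    if len(common) < 10:
        raise ValueError("need at least 10 genes with all three values")
    x = stats.rankdata(feature.loc[common])
    y = stats.rankdata(rank.rank.loc[common])
    z = stats.rankdata(control.rank.loc[common])
    if np.std(x) == 0 or np.std(y) == 0 or np.std(z) == 0:
        raise ValueError("constant vector in partial correlation")

    def _resid(v: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones(len(z)), z])
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx, ry = _resid(x), _resid(y)
    nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
    if nx < 1e-10 * np.linalg.norm(x) or ny < 1e-10 * np.linalg.norm(y):
        # feature (or rank) fully explained by the control: partial correlation 0
        return 0.0, 1.0
    rho = float(np.dot(rx, ry) / (nx * ny))
    n = len(common)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 3) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 3))
    return rho, p


def partial_spearman_table(
    features: pd.DataFrame, rank: VarianceRank, control: VarianceRank
) -> pd.DataFrame:
    """Batch partial Spearman over feature columns with BH adjustment."""
    rows = []
    for name in features.columns:
        rho, p = partial_spearman(features[name], rank, control)
        rows.append({"feature": name, "rho": rho, "p": p})
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = bh_adjust(frame["p"].to_numpy())
    return frame
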