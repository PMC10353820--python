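"""Decile-based functional statistics on the variance rank.

Covers: decile assignment, per-term decile entropy/skewness profiles,
hypergeometric gene-set enrichment with BH correction, Fisher tests of
environmental responsiveness for the rank tails, and the Poisson GLM of
per-gene environment counts on rank category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats.contingency import odds_ratio

from ._stats import bh_adjust
from .ranking import VarianceRank


@dataclass
class DecileProfile:
    """Counts of a term's genes across the 10 variance-rank deciles."""

    term_id: str
    counts: np.ndarray  # length 10, decile 1 = lowest variance
    n_genes: int
    entropy: float  # natural log; in [0, ln 10]
    skewness: float

    def __post_init__(self) -> None:
        if self.counts.sum() != self.n_genes:
            raise ValueError("decile counts must sum to n_genes")


@dataclass
class EnrichmentResult:
    set_id: str
    overlap: int
    expected: float
    fold: float
    p: float
    p_adjusted: float = np.nan
    direction: str = ""  # "high" or "low" tail context


def assign_deciles(rank: VarianceRank) -> pd.Series:
    """Decile 1..10 per gene: ceil(10 * rank / M); deterministic, no ties."""
    m = rank.n_genes
    if m < 10:
        raise ValueError("need at least 10 ranked genes")
    return np.ceil(10.0 * rank.rank / m).astype(int)


def decile_entropy(counts: np.ndarray) -> float:
    """Shannon entropy (natural log) of the decile proportions."""
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def decile_skewness(counts: np.ndarray) -> float:
    """Fisher-Pearson g1 of the multiset of decile indices.

    Mass concentrated in high deciles gives a left tail, hence negative skew;
    zero-variance profiles return 0 by convention.
    """
    idx = np.repeat(np.arange(1, 11), counts.astype(int))
    m = idx.mean()
    s2 = ((idx - m) ** 2).mean()
    if s2 == 0:
        return 0.0
    return float(((idx - m) ** 3).mean() / s2**1.5)


def term_decile_profile(
    term_genes: Iterable[str], deciles: pd.Series, min_genes: int = 100
) -> DecileProfile | None:
    """Decile count profile of a gene set with entropy and skewness.

    Returns None (with no profile) for terms whose intersection with the
    ranked genes is below ``min_genes``; raises on an empty intersection.
    """
    term_genes = set(term_genes)
    hit = deciles.loc[deciles.index.intersection(term_genes)]
    if hit.empty:
        raise ValueError("term has no genes in the ranked universe")
    if len(hit) < min_genes:
        return None
    counts = np.bincount(hit.to_numpy(), minlength=11)[1:]
    return DecileProfile(
        term_id="",
        counts=counts,
        n_genes=int(counts.sum()),
        entropy=decile_entropy(counts),
        skewness=decile_skewness(counts),
    )


def profile_terms(
    terms: Mapping[str, Iterable[str]], deciles: pd.Series, min_genes: int = 100
) -> pd.DataFrame:
    """Entropy/skewness table over all terms meeting the size filter."""
    rows = []
    for term_id, genes in terms.items():
        prof = term_decile_profile(genes, deciles, min_genes=min_genes)
        if prof is None:
            continue
        rows.append(
            {"term": term_id, "n_genes": prof.n_genes, "entropy": prof.entropy,
             "skewness": prof.skewness}
        )
    return pd.DataFrame(rows, columns=["term", "n_genes", "entropy", "skewness"])


def hypergeometric_enrichment(
    target: set[str], annotation: set[str], universe: set[str], set_id: str = ""
) -> EnrichmentResult:
    """Upper-tail hypergeometric p for the target/annotation overlap.

    fold = (overlap / |target|) / (|annotation| / |universe|).
    """
    if not universe:
        raise ValueError("empty universe")
    if not target <= universe or not annotation <= universe:
        raise ValueError("target and annotation must be subsets of the universe")
    n_u, n_t, n_a = len(universe), len(target), len(annotation)
    k = len(target & annotation)
    expected = n_t * n_a / n_u
    fold = (k / n_t) / (n_a / n_u) if n_t and n_a else np.nan
    p = float(stats.hypergeom.sf(k - 1, n_u, n_a, n_t))
    return EnrichmentResult(set_id=set_id, overlap=k, expected=expected, fold=fold, p=p)


def enrichment_table(
    target: set[str],
    annotations: Mapping[str, set[str]],
    universe: set[str],
    direction: str = "",
) -> pd.DataFrame:
    """Batch enrichment over many sets with BH-adjusted p-values."""
    results = [
        hypergeometric_enrichment(target, set(g) & universe, universe, set_id=name)
        for name, g in annotations.items()
    ]
    frame = pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "overlap": [r.overlap for r in results],
            "expected": [r.expected for r in results],
            "fold": [r.fold for r in results],
            "p": [r.p for r in results],
        }
    )
    frame["p_adjusted"] = bh_adjust(frame["p"].to_numpy())
    frame["direction"] = direction
    return frame


def _fisher_2x2(table: np.ndarray) -> dict[str, float]:
    res_two = stats.fisher_exact(table, alternative="two-sided")
    p_greater = stats.fisher_exact(table, alternative="greater")[1]
    p_less = stats.fisher_exact(table, alternative="less")[1]
    margins_ok = table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0
    odds = odds_ratio(table, kind="conditional").statistic if margins_ok else np.nan
    return {
        "odds": float(odds),
        "p_two_sided": float(res_two[1]),
        "p_greater": float(p_greater),
        "p_less": float(p_less),
    }


def env_responsiveness_tests(
    high: set[str],
    low: set[str],
    env: pd.DataFrame,
    universe: set[str],
) -> pd.DataFrame:
    """Fisher exact tests of tail-set membership vs environment response.

    For the high tail, the comparison universe excludes low-variance genes
    (and vice versa). One row per (tail, environment) plus an "any" row per
    tail for responding to >0 environments; BH adjustment is applied across
    the per-environment rows within each tail.
    """
    if not high <= universe or not low <= universe:
        raise ValueError("tail sets must be subsets of the universe")
    env = env.loc[env.index.intersection(universe)].astype(bool)
    responsive_any = set(env.index[env.any(axis=1)])

    rows = []
    for tail, tail_set, excluded in (("high", high, low), ("low", low, high)):
        background = (universe - excluded) | tail_set
        columns: list[tuple[str, set[str]]] = [("any", responsive_any)]
        columns += [(c, set(env.index[env[c]])) for c in env.columns]
        for env_name, responders in columns:
            in_tail = np.array([g in tail_set for g in background])
            resp = np.array([g in responders for g in background])
            table = np.array(
                [
                    [(in_tail & resp).sum(), (in_tail & ~resp).sum()],
                    [(~in_tail & resp).sum(), (~in_tail & ~resp).sum()],
                ]
            )
            row = {"tail": tail, "environment": env_name, **_fisher_2x2(table)}
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = np.nan
    for tail in ("high", "low"):
        sel = (frame["tail"] == tail) & (frame["environment"] != "any")
        frame.loc[sel, "p_adjusted"] = bh_adjust(frame.loc[sel, "p_two_sided"].to_numpy())
    return frame


def env_count_glm(env_count: pd.Series, category: pd.Series) -> pd.DataFrame:
    """Poisson log-link GLM of environment counts on gene category.

    ``category`` holds "high", "low" or "background" (the reference level).
    Fitted by IRLS; returns one row per non-reference category with the
    coefficient, Wald z and p, plus group medians.
    """
    cats = category.unique()
    if len(cats) < 2:
        raise ValueError("need at least 2 categories")
    y = env_count.loc[category.index].to_numpy(dtype=float)
    levels = [c for c in ("high", "low") if c in cats]
    design = np.column_stack(
        [np.ones(len(y))] + [(category == c).to_numpy(dtype=float) for c in levels]
    )
    model = sm.GLM(y, design, family=sm.families.Poisson())
    try:
        fit = model.fit()
    except Exception as err:  # pragma: no cover - IRLS failure surface
        raise RuntimeError(f"Poisson GLM IRLS failed to converge: {err}") from err
    medians = env_count.groupby(category).median()
    rows = []
    for k, level in enumerate(levels, start=1):
        rows.append(
            {
                "category": level,
                "coef": fit.params[k],
                "z": fit.tvalues[k],
                "p": fit.pvalues[k],
                "median": medians.get(level, np.nan),
                "median_background": medians.get("background", np.nan),
            }
        )
    return pd.DataFrame(rows)


def go_level3_terms(edges: pd.DataFrame, root: str) -> set[str]:
    """Terms at shortest-path depth 3 from ``root`` in a parent-child edge list.

    ``edges`` needs columns ``parent`` and ``child``; the root is depth 1, its
    children depth 2, and so on (matching the level-3 convention for GO).
    """
    children: dict[str, list[str]] = {}
    for parent, child in zip(edges["parent"], edges["child"]):
        children.setdefault(parent, []).append(child)
    depth = {root: 1}
    frontier = [root]
    while frontier:
        nxt = []
        for node in frontier:
            for ch in children.get(node, ()):
                if ch not in depth:
                    depth[ch] = depth[node] + 1
                    nxt.append(ch)
        frontier = nxt
    return {t for t, d in depth.items() if d == 3}
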