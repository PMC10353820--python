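"""Per-study pipeline from raw counts to per-gene residual mean and SD.

Stages (composed by :func:`run_study_pipeline`, each usable standalone):

1. keep control samples and sum technical replicates,
2. cpm expression filter (min 1 cpm in all samples, mean >= 5 cpm),
3. variance-stabilizing transformation (closed-form NB VST with a fitted
   parametric dispersion-mean trend, or a log2-cpm fallback),
4. OLS correction for study covariates,
5. robust-PCA Mahalanobis outlier-sample removal,

after which per-gene residual SDs (and pre-correction means) are summarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

_MAD_SCALE = 1.4826  # MAD -> SD under normality


@dataclass
class StudyBundle:
    """One study's counts plus sample metadata — the pipeline's unit of work."""

    study_id: str
    counts: pd.DataFrame  # gene x sample, non-negative integers
    metadata: pd.DataFrame  # indexed by sample_id
    tissue: str = ""
    source: str = "MISC"

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError(f"{self.study_id}: duplicated gene IDs")
        if self.counts.columns.has_duplicates:
            raise ValueError(f"{self.study_id}: duplicated sample IDs")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError(f"{self.study_id}: counts must be finite and >= 0")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class ExpressionMatrix:
    """Transformed gene x sample values with a provenance tag."""

    values: pd.DataFrame
    provenance: str  # "vst" or "residual"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")


@dataclass
class GeneSummary:
    """Per-gene mean/SD for one study after the full pipeline."""

    study_id: str
    mean: pd.Series
    sd: pd.Series
    n_samples_used: int
    genes_passing_filter: set[str] = field(default_factory=set)
    tissue: str = ""
    source: str = "MISC"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.mean.index, "mean": self.mean.values, "sd": self.sd.values,
             "n": self.n_samples_used}
        )


@dataclass
class PipelineConfig:
    covariates: Sequence[str] = ()
    min_cpm_all: float = 1.0
    min_cpm_mean: float = 5.0
    outlier_quantile: float = 0.99
    n_components: int | None = None  # None -> 70%-variance rule capped at 10
    transform: str = "vst"  # or "log2cpm"


# ---------------------------------------------------------------------------
# stage 1: controls + replicates


def select_controls_and_sum_replicates(bundle: StudyBundle) -> StudyBundle:
    """Drop non-control samples, then sum technical replicates column-wise.

    Covariates (all metadata columns other than sample_id) must agree within a
    replicate group; the collapsed sample takes the group ID as its sample ID.
    """
    meta = bundle.metadata
    if "replicate_group" not in meta.columns:
        raise ValueError(f"{bundle.study_id}: metadata lacks replicate_group")
    keep = meta["control"].astype(bool) if "control" in meta.columns else pd.Series(True, index=meta.index)
    meta = meta.loc[keep]
    counts = bundle.counts.loc[:, meta.index]

    new_cols, new_meta = {}, []
    check_cols = [c for c in meta.columns if c not in ("sample_id", "replicate_group")]
    for group, sub in meta.groupby("replicate_group", sort=False):
        for col in check_cols:
            if sub[col].nunique(dropna=False) > 1:
                raise ValueError(
                    f"{bundle.study_id}: conflicting {col!r} within replicate group {group!r}"
                )
        new_cols[str(group)] = counts.loc[:, sub.index].sum(axis=1)
        row = sub.iloc[0].copy()
        row["sample_id"] = str(group)
        new_meta.append(row)

    if not new_cols:
        raise ValueError(f"{bundle.study_id}: no control samples remain")
    out_meta = pd.DataFrame(new_meta).set_index("sample_id", drop=False)
    return StudyBundle(
        study_id=bundle.study_id,
        counts=pd.DataFrame(new_cols, index=bundle.counts.index),
        metadata=out_meta,
        tissue=bundle.tissue,
        source=bundle.source,
    )


# ---------------------------------------------------------------------------
# stage 2: cpm filter


def filter_genes_by_cpm(
    bundle: StudyBundle, min_cpm_all: float = 1.0, min_cpm_mean: float = 5.0
) -> StudyBundle:
    """Keep genes with cpm >= ``min_cpm_all`` in every sample and mean cpm
    >= ``min_cpm_mean``; library sizes are per-sample totals over all
    pre-filter genes."""
    if bundle.n_samples < 1:
        raise ValueError("need at least one sample")
    lib = bundle.counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError(f"{bundle.study_id}: zero library size")
    cpm = bundle.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    keep = (cpm.min(axis=1) >= min_cpm_all) & (cpm.mean(axis=1) >= min_cpm_mean)
    if not keep.any():
        raise ValueError(
            f"{bundle.study_id}: cpm filter removed every gene; "
            f"lower min_cpm_all/min_cpm_mean ({min_cpm_all}, {min_cpm_mean})"
        )
    return StudyBundle(
        study_id=bundle.study_id,
        counts=bundle.counts.loc[keep],
        metadata=bundle.metadata,
        tissue=bundle.tissue,
        source=bundle.source,
    )


# ---------------------------------------------------------------------------
# stage 3: VST


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over genes positive in all samples."""
    pos = (counts > 0).all(axis=1)
    if pos.sum() >= 1:
        loggeo = np.log(counts[pos]).mean(axis=1)
        sf = np.exp(np.median(np.log(counts[pos]) - loggeo[:, None], axis=0))
    else:
        sf = counts.sum(axis=0) / 1e6
    return sf / np.exp(np.mean(np.log(sf)))


def _fit_dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of disp ~ a0/mean + a1 with a0, a1 >= 0.

    Non-positive method-of-moments estimates (under-dispersed genes) are
    floored at a tiny positive value so Poisson-like data still yields a fit.
    """
    ok = (mean > 0) & np.isfinite(disp)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 genes available for dispersion trend fitting")
    d = np.maximum(disp[ok], 1e-8)
    design = np.column_stack([1.0 / mean[ok], np.ones(ok.sum())])
    coef, _ = nnls(design, d)
    return float(coef[0]), float(coef[1])


def variance_stabilize(bundle: StudyBundle, transform: str = "vst") -> ExpressionMatrix:
    """Closed-form NB VST after median-of-ratios normalization.

    Per-gene method-of-moments dispersions are fitted to the parametric trend
    disp(mu) = a0/mu + a1 (non-negative least squares) and the matching
    closed-form transform

        vst(q) = log2((1 + a0 + 2*a1*q + 2*sqrt(a1*q*(1 + a0 + a1*q))) / (4*a1))

    is applied to the normalized counts q. Monotone in q per sample and
    approximately removes the NB variance-mean trend; exact agreement with any
    particular external implementation is a non-goal. ``transform="log2cpm"``
    selects the log2(cpm + 0.5) fallback.
    """
    counts = bundle.counts.to_numpy(dtype=float)
    if transform == "log2cpm":
        lib = counts.sum(axis=0)
        vals = np.log2(counts / lib[None, :] * 1e6 + 0.5)
        return ExpressionMatrix(
            values=pd.DataFrame(vals, index=bundle.counts.index, columns=bundle.counts.columns),
            provenance="vst",
        )
    if transform != "vst":
        raise ValueError(f"unknown transform {transform!r}")

    sf = _size_factors(counts)
    q = counts / sf[None, :]
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - mu) / mu**2
    a0, a1 = _fit_dispersion_trend(mu, disp)
    a1 = max(a1, 1e-8)  # guard: trend must curve over to log-like behavior
    inner = (1.0 + a0 + 2.0 * a1 * q + 2.0 * np.sqrt(a1 * q * (1.0 + a0 + a1 * q))) / (4.0 * a1)
    vals = np.log2(inner)
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=bundle.counts.index, columns=bundle.counts.columns),
        provenance="vst",
    )


# ---------------------------------------------------------------------------
# stage 4: covariate correction


def _design_matrix(metadata: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(metadata))]
    for cov in covariates:
        if cov not in metadata.columns:
            raise ValueError(f"covariate {cov!r} absent from metadata")
        col = metadata[cov]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            x = col.to_numpy(dtype=float)
            sd = x.std()
            cols.append((x - x.mean()) / sd if sd > 0 else np.zeros_like(x))
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
    design = np.column_stack(cols)
    # drop aliased columns (rank-revealing QR via pivoted least squares)
    keep = [0]
    for j in range(1, design.shape[1]):
        trial = design[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping aliased design column %d", j)
    return design[:, keep]


def correct_covariates(
    expr: ExpressionMatrix, metadata: pd.DataFrame, covariates: Sequence[str]
) -> ExpressionMatrix:
    """Per-gene OLS residuals on intercept + dummy-coded categoricals +
    standardized continuous covariates. Residuals are orthogonal to every
    retained design column; aliased columns are dropped with a warning."""
    meta = metadata.loc[expr.values.columns]
    design = _design_matrix(meta, covariates)
    y = expr.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return ExpressionMatrix(
        values=pd.DataFrame(resid.T, index=expr.values.index, columns=expr.values.columns),
        provenance="residual",
    )


# ---------------------------------------------------------------------------
# stage 5: outlier removal


def _robust_components(x: np.ndarray, n_components: int | None) -> np.ndarray:
    """Scores of samples on robust principal components.

    Genes are centered by median and scaled by MAD (constant genes dropped);
    components come from the SVD of the robustly standardized matrix. With
    ``n_components=None`` the number of axes is the smallest explaining 70% of
    the variance, capped at 10.
    """
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med[None, :]), axis=0) * _MAD_SCALE
    ok = mad > 0
    z = (x[:, ok] - med[None, ok]) / mad[None, ok]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    if n_components is None:
        frac = np.cumsum(s**2) / np.sum(s**2)
        n_components = min(int(np.searchsorted(frac, 0.70) + 1), 10)
    n_components = min(n_components, len(s))
    return u[:, :n_components] * s[None, :n_components]


def remove_outlier_samples(
    expr: ExpressionMatrix, quantile: float = 0.99, n_components: int | None = None
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples whose robust Mahalanobis distance exceeds the empirical
    ``quantile`` of the distance distribution (strict inequality).

    Distances are computed in robust-PC space against the componentwise median
    with a MAD-scaled diagonal covariance.
    """
    vals = expr.values.to_numpy(dtype=float).T  # samples x genes
    n = vals.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for outlier detection")
    if n_components is not None and n_components >= n:
        raise ValueError("n_components must be < n_samples")
    scores = _robust_components(vals, n_components)
    center = np.median(scores, axis=0)
    scale = np.median(np.abs(scores - center[None, :]), axis=0) * _MAD_SCALE
    scale[scale == 0] = 1.0
    dist = np.sqrt((((scores - center[None, :]) / scale[None, :]) ** 2).sum(axis=1))
    cutoff = np.quantile(dist, quantile)  # linear interpolation
    keep = dist <= cutoff
    outliers = list(expr.values.columns[~keep])
    return (
        ExpressionMatrix(values=expr.values.loc[:, keep], provenance=expr.provenance),
        outliers,
    )


# ---------------------------------------------------------------------------
# stage 6: summary


def summarize_genes(
    expr: ExpressionMatrix, mean_source: ExpressionMatrix | None = None, study_id: str = ""
) -> GeneSummary:
    """Per-gene sample mean and SD (n-1 denominator).

    OLS residual means are identically 0, so when ``mean_source`` is given
    (the pre-correction VST matrix restricted to surviving samples) the
    reported mean comes from it while the SD comes from ``expr``.
    """
    vals = expr.values
    if vals.shape[1] < 4:
        raise ValueError("need at least 4 samples to summarize")
    sd = vals.std(axis=1, ddof=1)
    if mean_source is not None:
        mean = mean_source.values.loc[vals.index, vals.columns].mean(axis=1)
    else:
        mean = vals.mean(axis=1)
    return GeneSummary(
        study_id=study_id,
        mean=mean,
        sd=sd,
        n_samples_used=vals.shape[1],
        genes_passing_filter=set(vals.index),
    )


# ---------------------------------------------------------------------------
# composition


@dataclass
class PipelineDiagnostics:
    stage_counts: pd.DataFrame  # genes/samples surviving each stage
    mean_sd_before: pd.DataFrame  # per-gene mean/SD on log2(cpm+0.5) scale
    mean_sd_after: pd.DataFrame  # per-gene mean/SD after VST + correction
    pca_before: pd.DataFrame  # sample coordinates, first 2 PCs, pre-correction
    pca_after: pd.DataFrame  # post-correction, post-outlier-removal
    outlier_samples: list[str] = field(default_factory=list)


def _pca_coords(values: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    x = values.to_numpy(dtype=float).T
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(k, len(s))
    return pd.DataFrame(
        u[:, :k] * s[None, :k], index=values.columns, columns=[f"PC{i+1}" for i in range(k)]
    )


def run_study_pipeline(
    bundle: StudyBundle, config: PipelineConfig | None = None
) -> tuple[GeneSummary, PipelineDiagnostics]:
    """Compose the five stages in order and summarize; deterministic."""
    cfg = config or PipelineConfig()
    counts0 = bundle.counts.shape

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"{bundle.study_id}: stage {name!r} failed: {err}") from err

    b = _stage("controls_replicates", select_controls_and_sum_replicates, bundle)
    shape_controls = b.counts.shape
    b = _stage("cpm_filter", filter_genes_by_cpm, b, cfg.min_cpm_all, cfg.min_cpm_mean)

    lib = b.counts.sum(axis=0).to_numpy(dtype=float)
    logcpm = np.log2(b.counts.to_numpy(dtype=float) / lib[None, :] * 1e6 + 0.5)
    mean_sd_before = pd.DataFrame(
        {"mean": logcpm.mean(axis=1), "sd": logcpm.std(axis=1, ddof=1)}, index=b.counts.index
    )

    vst = _stage("vst", variance_stabilize, b, cfg.transform)
    pca_before = _pca_coords(vst.values)
    resid = _stage("covariates", correct_covariates, vst, b.metadata, cfg.covariates)
    resid, outliers = _stage(
        "outliers", remove_outlier_samples, resid, cfg.outlier_quantile, cfg.n_components
    )
    pca_after = _pca_coords(resid.values)
    vst_kept = ExpressionMatrix(
        values=vst.values.loc[:, resid.values.columns], provenance="vst"
    )
    summary = _stage("summary", summarize_genes, resid, vst_kept, bundle.study_id)
    summary.tissue, summary.source = bundle.tissue, bundle.source

    mean_sd_after = pd.DataFrame(
        {"mean": summary.mean, "sd": summary.sd}, index=resid.values.index
    )
    stage_counts = pd.DataFrame(
        {
            "stage": ["input", "controls_replicates", "cpm_filter", "outlier_removal"],
            "n_genes": [counts0[0], shape_controls[0], b.counts.shape[0], resid.values.shape[0]],
            "n_samples": [counts0[1], shape_controls[1], b.counts.shape[1], resid.values.shape[1]],
        }
    )
    diag = PipelineDiagnostics(
        stage_counts=stage_counts,
        mean_sd_before=mean_sd_before,
        mean_sd_after=mean_sd_after,
        pca_before=pca_before,
        pca_after=pca_after,
        outlier_samples=outliers,
    )
    return summary, diag
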