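"""Synthetic multi-study expression data with known ground truth.

Every input the downstream pipeline consumes can be generated here: per-study
negative-binomial count matrices with a shared latent variance propensity,
batch/covariate structure and outlier samples; decile-skewed gene-set
annotations and binary labels; dyadic Fisher-z correlation tables drawn from
the random-effects model the fitting module estimates; and toy genomic window
tracks, chromatin segmentations and gene regions.

The generative process for inter-individual variance is a stand-in (per-sample
log-normal noise on the NB mean, with noise SD a monotone function of the
realized propensity); the quantity the pipeline is meant to recover is the
*rank* of the shared propensity, which is well-defined regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .dyadic import DyadTable, source_pair_index
from .preprocess import StudyBundle

_SOURCES = ("GTEX", "TCGA", "MISC")

# noise SD (natural-log scale) spanned by the propensity -> variance map
_SIGMA_LO = 0.15
_SIGMA_HI = 1.05
_OUTLIER_NOISE_MULT = 4.0
_BATCH_EFFECT_SD = 0.3
_COVARIATE_EFFECT_SD = 0.1
_LIBRARY_LOG_SD = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the multi-study generator.

    ``consistency`` is the fraction of the variance-propensity signal shared
    across studies; 1 makes every study rank genes identically (up to sampling
    noise), 0 makes the per-study propensities independent.
    """

    n_genes: int = 2000
    n_studies: int = 10
    samples_per_study: int | Sequence[int] = 100
    tissue_labels: Sequence[str] | None = None
    source_labels: Sequence[str] | None = None
    consistency: float = 0.9
    dispersion_baseline: float = 0.05
    batch_levels: int = 1
    outlier_fraction: float = 0.0
    seed: int = 0

    def samples(self) -> list[int]:
        if isinstance(self.samples_per_study, int):
            return [self.samples_per_study] * self.n_studies
        return [int(n) for n in self.samples_per_study]

    def tissues(self) -> list[str]:
        if self.tissue_labels is None:
            # pair up studies by tissue so tissue-congruent dyads exist
            return [f"tissue{i // 2}" for i in range(self.n_studies)]
        return list(self.tissue_labels)

    def sources(self) -> list[str]:
        if self.source_labels is None:
            return [_SOURCES[i % 3] for i in range(self.n_studies)]
        return [str(s) for s in self.source_labels]

    def validate(self) -> None:
        if not (0.0 <= self.consistency <= 1.0):
            raise ValueError(f"consistency must be in [0, 1], got {self.consistency}")
        if not (0.0 <= self.outlier_fraction < 0.5):
            raise ValueError(f"outlier_fraction must be in [0, 0.5), got {self.outlier_fraction}")
        if min(self.n_genes, self.n_studies, self.batch_levels) < 1:
            raise ValueError("n_genes, n_studies and batch_levels must all be >= 1")
        if not np.isfinite(self.dispersion_baseline) or self.dispersion_baseline <= 0:
            raise ValueError("dispersion_baseline must be a finite positive real")
        if any(n < 4 for n in self.samples()):
            raise ValueError("samples_per_study must be >= 4 (SD undefined after corrections)")
        if len(self.tissues()) != self.n_studies or len(self.sources()) != self.n_studies:
            raise ValueError("tissue/source label lists must have one entry per study")
        bad = set(self.sources()) - set(_SOURCES)
        if bad:
            raise ValueError(f"unknown source labels: {sorted(bad)}")


@dataclass
class DyadicTruth:
    """Generative parameter values of the dyadic correlation model."""

    mu0: float
    beta: np.ndarray  # length 2, tissue congruence levels
    gamma: np.ndarray  # length 6, source-pair levels
    sigma: float
    sigma_alpha: float
    alpha: np.ndarray | None = None  # realized per-study effects


@dataclass
class TruthRecord:
    """Ground truth of one simulated study panel."""

    gene_ids: list[str]
    true_log_mean: np.ndarray
    true_variance_propensity: np.ndarray  # latent shared component
    realized_propensity: np.ndarray  # gene x study
    outlier_sample_ids: dict[str, set[str]] = field(default_factory=dict)
    dyadic_truth: DyadicTruth | None = None

    def propensity_rank(self) -> np.ndarray:
        """Ranks 1..n_genes of the shared propensity (1 = lowest)."""
        order = np.argsort(self.true_variance_propensity, kind="stable")
        ranks = np.empty(len(order), dtype=int)
        ranks[order] = np.arange(1, len(order) + 1)
        return ranks

    def propensity_deciles(self) -> np.ndarray:
        r = self.propensity_rank()
        return np.ceil(10.0 * r / len(r)).astype(int)


def _noise_sd(propensity: np.ndarray) -> np.ndarray:
    return _SIGMA_LO + (_SIGMA_HI - _SIGMA_LO) * expit(propensity)


def generate_multistudy_counts(config: SimConfig) -> tuple[list[StudyBundle], TruthRecord]:
    """Draw one study panel: NB counts + metadata per study, and the truth.

    Per study, counts are NB with gene mean
    ``exp(true_log_mean + batch + covariate + eps) * library/1e6`` where the
    per-sample biological noise ``eps`` has SD monotone in the realized
    propensity ``consistency*shared + (1-consistency)*study noise``. Outlier
    samples get their noise SD multiplied by 4. Identical config (incl. seed)
    gives bit-identical output.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    g_seed, *study_seeds = root.spawn(config.n_studies + 1)
    rng = np.random.default_rng(g_seed)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    log_mean = rng.normal(np.log(100.0), 1.2, size=config.n_genes)
    shared = rng.normal(0.0, 1.0, size=config.n_genes)

    realized = np.empty((config.n_genes, config.n_studies))
    bundles: list[StudyBundle] = []
    truth = TruthRecord(
        gene_ids=genes,
        true_log_mean=log_mean,
        true_variance_propensity=shared,
        realized_propensity=realized,
    )

    tissues, sources, sizes = config.tissues(), config.sources(), config.samples()
    for s, seed_s in enumerate(study_seeds):
        srng = np.random.default_rng(seed_s)
        study_id = f"study{s:02d}"
        n = sizes[s]
        noise = srng.normal(0.0, 1.0, size=config.n_genes)
        realized[:, s] = config.consistency * shared + (1.0 - config.consistency) * noise
        sd = _noise_sd(realized[:, s])

        batch = srng.integers(0, config.batch_levels, size=n)
        batch_eff = srng.normal(0.0, _BATCH_EFFECT_SD, size=(config.n_genes, config.batch_levels))
        batch_eff[:, 0] = 0.0
        age = srng.uniform(20.0, 70.0, size=n)
        age_std = (age - age.mean()) / age.std()
        age_slope = srng.normal(0.0, _COVARIATE_EFFECT_SD, size=config.n_genes)

        n_out = int(np.floor(config.outlier_fraction * n))
        out_idx = srng.choice(n, size=n_out, replace=False)
        mult = np.ones(n)
        mult[out_idx] = _OUTLIER_NOISE_MULT

        eps = srng.normal(0.0, 1.0, size=(config.n_genes, n)) * sd[:, None] * mult[None, :]
        library = np.exp(srng.normal(np.log(1e6), _LIBRARY_LOG_SD, size=n))
        log_mu = (
            log_mean[:, None]
            + batch_eff[:, batch]
            + age_slope[:, None] * age_std[None, :]
            + eps
        )
        mu = np.exp(log_mu) * (library[None, :] / 1e6)
        # gamma-Poisson mixture == NB(mean mu, dispersion d): var = mu + d*mu^2
        d = config.dispersion_baseline
        lam = srng.gamma(shape=1.0 / d, scale=mu * d)
        counts = srng.poisson(lam)

        sample_ids = [f"{study_id}_s{i:04d}" for i in range(n)]
        meta = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "study_id": study_id,
                "tissue": tissues[s],
                "source": sources[s],
                "batch": [f"b{b}" for b in batch],
                "age": age,
                "control": True,
                "replicate_group": sample_ids,
            }
        ).set_index("sample_id", drop=False)
        bundles.append(
            StudyBundle(
                study_id=study_id,
                counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
                metadata=meta,
                tissue=tissues[s],
                source=sources[s],
            )
        )
        truth.outlier_sample_ids[study_id] = {sample_ids[i] for i in out_idx}

    return bundles, truth


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationSet:
    terms: dict[str, list[str]]  # GMT-style gene sets
    labels: pd.DataFrame  # boolean columns: housekeeping, ieg
    env: pd.DataFrame  # boolean gene x environment responsiveness


def _decile_weights(skew: str) -> np.ndarray:
    d = np.arange(1, 11, dtype=float)
    if skew == "uniform":
        return np.ones(10)
    if skew == "low-biased":
        return 11.0 - d
    if skew == "high-biased":
        return d
    raise ValueError(f"target_skew must be uniform/low-biased/high-biased, got {skew!r}")


def _sample_term(
    rng: np.random.Generator, genes: np.ndarray, deciles: np.ndarray, size: int, skew: str
) -> list[str]:
    w = _decile_weights(skew)[deciles - 1]
    p = w / w.sum()
    idx = rng.choice(len(genes), size=size, replace=False, p=p)
    return sorted(genes[np.sort(idx)])


def generate_annotations(
    config: SimConfig,
    truth: TruthRecord,
    term_spec: Sequence[tuple[str, int, str]],
    n_env: int = 10,
    env_base_rate: float = 0.2,
    env_effect: float = 0.0,
    env_breadth: float = 0.3,
) -> AnnotationSet:
    """Gene sets with decile-targeted skew plus binary label columns.

    ``term_spec`` rows are (term_id, n_genes, target_skew). Terms sample genes
    with per-decile weights against the true propensity rank. The label frame
    has housekeeping-like (low-decile-biased) and IEG-like (high-decile-biased)
    columns. Environment responsiveness uses a Gaussian copula: ``env_breadth``
    is the across-environment latent correlation, ``env_effect`` shifts the
    response threshold linearly in decile (0 = exact null with marginal rate
    ``env_base_rate``).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    genes = np.asarray(truth.gene_ids)
    deciles = truth.propensity_deciles()

    terms: dict[str, list[str]] = {}
    for term_id, size, skew in term_spec:
        if size < 1:
            raise ValueError(f"term {term_id}: size must be >= 1")
        if size > len(genes):
            raise ValueError(f"term {term_id}: size {size} exceeds n_genes {len(genes)}")
        terms[term_id] = _sample_term(rng, genes, deciles, size, skew)

    n_label = max(len(genes) // 10, 10)
    labels = pd.DataFrame(False, index=genes, columns=["housekeeping", "ieg"])
    labels.loc[_sample_term(rng, genes, deciles, n_label, "low-biased"), "housekeeping"] = True
    labels.loc[_sample_term(rng, genes, deciles, n_label, "high-biased"), "ieg"] = True

    if not (0.0 <= env_breadth < 1.0):
        raise ValueError("env_breadth must be in [0, 1)")
    shift = env_effect * (deciles - 5.5) / 4.5
    u = rng.normal(size=len(genes))
    e = rng.normal(size=(len(genes), n_env))
    z = np.sqrt(env_breadth) * u[:, None] + np.sqrt(1.0 - env_breadth) * e + shift[:, None]
    thresh = -ndtri(env_base_rate)  # P(z > thresh) = base rate when shift = 0
    env = pd.DataFrame(
        z > thresh, index=genes, columns=[f"env{k}" for k in range(1, n_env + 1)]
    )
    return AnnotationSet(terms=terms, labels=labels, env=env)


# ---------------------------------------------------------------------------
# dyadic correlations


def generate_dyadic_correlations(
    tissues: Sequence[str],
    sources: Sequence[str],
    params: DyadicTruth,
    seed: int = 0,
) -> tuple[DyadTable, DyadicTruth]:
    """Draw all ``n(n-1)/2`` Fisher-z dyads from the random-effects model.

    ``z_ij ~ N(mu0 + a_i + a_j + beta_t + gamma_so, sigma)`` with
    ``a_i ~ N(0, sigma_alpha)``; congruence codings match the fitting module.
    Returns the table and a copy of the truth with the realized alphas.
    """
    n = len(tissues)
    if n < 3:
        raise ValueError("need at least 3 studies for identifiable dyads")
    if len(sources) != n:
        raise ValueError("tissues and sources must have equal length")
    for val in (params.mu0, params.sigma, params.sigma_alpha, *params.beta, *params.gamma):
        if not np.isfinite(val):
            raise ValueError("dyadic parameters must be finite")
    if params.sigma <= 0 or params.sigma_alpha <= 0:
        raise ValueError("sigma and sigma_alpha must be > 0")

    rng = np.random.default_rng(seed)
    alpha = rng.normal(0.0, params.sigma_alpha, size=n)
    study_ids = [f"study{i:02d}" for i in range(n)]
    rows = []
    for i in range(n):
        for j in range(i):
            t = 1 if tissues[i] == tissues[j] else 2
            so = source_pair_index(sources[i], sources[j])
            mu = params.mu0 + alpha[i] + alpha[j] + params.beta[t - 1] + params.gamma[so - 1]
            rows.append(
                {
                    "study_i": study_ids[i],
                    "study_j": study_ids[j],
                    "z": rng.normal(mu, params.sigma),
                    "t_index": t,
                    "so_index": so,
                }
            )
    table = DyadTable(
        dyads=pd.DataFrame(rows),
        study_ids=study_ids,
        sources=[str(s).upper() for s in sources],
    )
    realized = DyadicTruth(
        mu0=params.mu0,
        beta=np.asarray(params.beta, dtype=float),
        gamma=np.asarray(params.gamma, dtype=float),
        sigma=params.sigma,
        sigma_alpha=params.sigma_alpha,
        alpha=alpha,
    )
    return table, realized


# ---------------------------------------------------------------------------
# genomic tracks

_GENE_LEN = 2000
_GENE_GAP = 1000


@dataclass
class GenomicTracks:
    windows: pd.DataFrame  # chrom, start, end, value (bedGraph-like)
    segmentation: pd.DataFrame  # chrom, start, end, state (partition)
    regions: pd.DataFrame  # gene, chrom, start, end, strand
    chrom_length: int


def generate_genomic_tracks(
    config: SimConfig,
    truth: TruthRecord,
    window_size: int = 10_000,
    effect: float = 0.5,
) -> GenomicTracks:
    """Toy chromosome: gene regions, a window metric correlated with the
    propensity rank at strength ``effect``, and a chromatin-state partition
    whose within-gene state composition is biased by propensity decile."""
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    if not (0.0 <= effect <= 1.0):
        raise ValueError("effect must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    n = config.n_genes
    chrom = "chrS"
    starts = _GENE_GAP + np.arange(n) * (_GENE_LEN + _GENE_GAP)
    ends = starts + _GENE_LEN
    chrom_length = int(ends[-1] + _GENE_GAP)
    if ends[-1] > chrom_length:
        raise ValueError("genes exceed chromosome length")

    regions = pd.DataFrame(
        {
            "gene": truth.gene_ids,
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
        }
    )

    scaled_rank = (truth.propensity_rank() - 1) / max(n - 1, 1)
    value = effect * scaled_rank + (1.0 - effect) * rng.uniform(size=n)

    w_starts = np.arange(0, chrom_length, window_size)
    w_ends = np.minimum(w_starts + window_size, chrom_length)
    w_val = rng.uniform(size=len(w_starts))
    # windows overlapping >=1 gene take the mean metric of the overlapped genes
    for k, (ws, we) in enumerate(zip(w_starts, w_ends)):
        hit = (starts < we) & (ends > ws)
        if hit.any():
            w_val[k] = value[hit].mean()
    windows = pd.DataFrame({"chrom": chrom, "start": w_starts, "end": w_ends, "value": w_val})

    deciles = truth.propensity_deciles()
    seg_rows = []
    cursor = 0
    for g in range(n):
        if starts[g] > cursor:
            seg_rows.append((chrom, cursor, starts[g], "Quies"))
        frac_active = 0.1 + 0.08 * (deciles[g] - 1)  # 0.1 .. 0.82 by decile
        cut = starts[g] + int(round(frac_active * _GENE_LEN))
        if cut > starts[g]:
            seg_rows.append((chrom, starts[g], cut, "Active"))
        if ends[g] > cut:
            seg_rows.append((chrom, cut, ends[g], "Repressed"))
        cursor = int(ends[g])
    if cursor < chrom_length:
        seg_rows.append((chrom, cursor, chrom_length, "Quies"))
    segmentation = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "state"])

    return GenomicTracks(
        windows=windows,
        segmentation=segmentation,
        regions=regions,
        chrom_length=chrom_length,
    )
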