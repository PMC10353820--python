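# txvar

Cross-study analysis of gene expression variance: per-study estimation of
residual expression standard deviations from RNA-seq counts, correlation of
those SD profiles across studies, a Bayesian dyadic model of the pairwise
correlation structure, a consensus gene variance rank built by PC1 projection,
and the functional/regulatory statistics defined on that rank. A synthetic
multi-study generator with known ground truth stands in for real repositories,
so everything is testable offline.

## Modules

| Module | Role |
| --- | --- |
| `txvar.simulate` | Multi-study negative-binomial counts with a shared latent variance propensity, batch/covariate structure and outlier samples; decile-skewed gene sets and binary labels; dyadic Fisher-z tables drawn from the random-effects model; toy genomic tracks/segmentations. |
| `txvar.preprocess` | Per-study pipeline: control selection + replicate summing → cpm filter (≥1 cpm in all samples, mean ≥5) → closed-form NB variance-stabilizing transform → OLS covariate correction → robust-PCA Mahalanobis outlier removal → per-gene residual mean/SD. |
| `txvar.crossstudy` | Gene×study SD/mean matrices (union of genes, NaN where filtered), complete-case Spearman correlation matrix between studies, PCoA on `|1 − ρ|` distances. |
| `txvar.dyadic` | Bayesian dyadic random-effects model for Fisher-z study-pair correlations with a self-contained adaptive Metropolis-within-Gibbs sampler (Gaussian Gibbs block for the study effects, ridge moves for the confounded intercept directions), split R-hat and Geyer ESS diagnostics. |
| `txvar.ranking` | Across-study and tissue-level consensus ranks: rank-transform per study, PCA-impute missing cells (≥50% presence rule), project each gene's centered rank profile onto PC1 of the study correlation matrix. |
| `txvar.annotations` | Decile assignment, per-term decile entropy (natural log) and Fisher–Pearson skewness, hypergeometric enrichment with BH, Fisher tests of environmental responsiveness, Poisson GLM of environment counts on rank category. |
| `txvar.features` | Co-expression weighted connectivity (BH-trimmed Spearman graph), window-track metrics per gene, chromatin-state proportions of flanked gene regions, rank tests between rank-tail groups, partial Spearman correlations controlling for the mean rank. |

## CLI

Each pipeline stage is a subcommand of `txvar`:

```sh
txvar simulate --n-genes 2000 --n-studies 10 --samples 100 --seed 1 --out sim/
txvar preprocess --counts sim/study00_counts.tsv --metadata sim/metadata.csv \
    --study-id study00 --out summaries/study00_summary.tsv
txvar correlate --summaries-dir summaries/ --out corr/    # needs summaries/studies.csv
txvar rank --sd-matrix corr/sd_matrix.tsv --mean-matrix corr/mean_matrix.tsv --out ranks/
txvar fit-model --dyads dyads.tsv --chains 4 --warmup 1000 --sampling 1000 --seed 1 --out fit/
txvar enrich --rank ranks/variance_rank.tsv --gmt sets.gmt --labels labels.tsv --out enrich/
txvar features --regions genes.bed --track pi.bedgraph --segmentation states.bed \
    --rank ranks/variance_rank.tsv --mean-rank ranks/mean_rank.tsv --out features/
```

All formats are plain text: counts as gene×sample TSV (or MatrixMarket),
metadata CSV, gene sets GMT, SD matrices TSV with `NA` tokens, genomic inputs
as bedGraph/BED (0-based half-open).

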