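"""Plain-text readers and writers for the formats the pipeline consumes.

Counts: gene x sample TSV (genes as rows, header = sample IDs) or MatrixMarket
with row/column ID sidecar files. Metadata: CSV with required columns
study_id, sample_id. Gene sets: GMT. Labels: two-column TSV. Genomic inputs:
bedGraph-like window tracks and BED segmentations / gene regions, 0-based
half-open, track lines skipped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

NA_TOKEN = "NA"


# ---------------------------------------------------------------------------
# counts + metadata


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    return counts


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_mtx(mtx: str | Path, genes: str | Path, samples: str | Path) -> pd.DataFrame:
    from scipy.io import mmread

    raw = mmread(str(mtx))
    mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
    gene_ids = Path(genes).read_text().split()
    sample_ids = Path(samples).read_text().split()
    return pd.DataFrame(mat, index=gene_ids, columns=sample_ids)


def write_counts_mtx(counts: pd.DataFrame, mtx: str | Path, genes: str | Path, samples: str | Path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(mtx), csr_matrix(counts.to_numpy()))
    Path(genes).write_text("\n".join(map(str, counts.index)) + "\n")
    Path(samples).write_text("\n".join(map(str, counts.columns)) + "\n")


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    for col in ("study_id", "sample_id"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    return meta.set_index("sample_id", drop=False)


def write_metadata_csv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# summaries and matrices


def write_gene_summary_tsv(summary, path: str | Path) -> None:
    summary.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_summary_tsv(path: str | Path, study_id: str = "", tissue: str = "", source: str = "MISC"):
    from .preprocess import GeneSummary

    frame = pd.read_csv(path, sep="\t")
    frame = frame.set_index("gene")
    return GeneSummary(
        study_id=study_id or Path(path).stem,
        mean=frame["mean"],
        sd=frame["sd"],
        n_samples_used=int(frame["n"].iloc[0]),
        genes_passing_filter=set(frame.index),
        tissue=tissue,
        source=source,
    )


def write_matrix_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="gene")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])


# ---------------------------------------------------------------------------
# gene sets and labels


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    terms: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        terms[fields[0]] = [g for g in fields[2:] if g]
    return terms


def write_gmt(terms: Mapping[str, list[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, description or term, *genes]) + "\n")


def read_labels_tsv(path: str | Path) -> pd.DataFrame:
    """Two-or-more-column TSV: gene then one binary (0/1) column per label."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.astype(bool)


def write_labels_tsv(labels: pd.DataFrame, path: str | Path) -> None:
    labels.astype(int).to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# genomic intervals


def _read_interval_file(path: str | Path, columns: list[str]) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        rows.append(line.rstrip("\n").split("\t")[: len(columns)])
    frame = pd.DataFrame(rows, columns=columns)
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    return frame


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    frame = _read_interval_file(path, ["chrom", "start", "end", "value"])
    frame["value"] = frame["value"].astype(float)
    return frame


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed_states(path: str | Path) -> pd.DataFrame:
    return _read_interval_file(path, ["chrom", "start", "end", "state"])


def write_bed_states(segmentation: pd.DataFrame, path: str | Path) -> None:
    segmentation[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed_regions(path: str | Path) -> pd.DataFrame:
    frame = _read_interval_file(path, ["chrom", "start", "end", "gene", "score", "strand"])
    if frame["strand"].isna().any():
        frame["strand"] = frame["strand"].fillna("+")
    return frame[["gene", "chrom", "start", "end", "strand"]]


def write_bed_regions(regions: pd.DataFrame, path: str | Path) -> None:
    out = regions.copy()
    out["score"] = 0
    out[["chrom", "start", "end", "gene", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# truth + config echo


def write_truth_tsv(truth, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "gene": truth.gene_ids,
            "true_log_mean": truth.true_log_mean,
            "true_variance_propensity": truth.true_variance_propensity,
        }
    )
    realized = pd.DataFrame(
        truth.realized_propensity,
        columns=[f"realized_study{s:02d}" for s in range(truth.realized_propensity.shape[1])],
    )
    pd.concat([frame, realized], axis=1).to_csv(path, sep="\t", index=False)


def write_config_echo(config, path: str | Path) -> None:
    payload = {k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in vars(config).items()}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
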