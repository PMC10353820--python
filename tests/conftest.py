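import numpy as np
import pandas as pd
import pytest

from txvar import simulate
from txvar.preprocess import StudyBundle


@pytest.fixture(scope="session")
def small_panel():
    """4 studies x 500 genes x 60 samples with batch and outliers."""
    cfg = simulate.SimConfig(
        n_genes=500,
        n_studies=4,
        samples_per_study=60,
        consistency=0.9,
        batch_levels=2,
        outlier_fraction=0.02,
        seed=11,
    )
    return cfg, *simulate.generate_multistudy_counts(cfg)


@pytest.fixture(scope="session")
def clean_panel():
    """3 studies, no batch structure, no outliers, high consistency."""
    cfg = simulate.SimConfig(
        n_genes=300,
        n_studies=3,
        samples_per_study=80,
        consistency=1.0,
        batch_levels=1,
        outlier_fraction=0.0,
        seed=5,
    )
    return cfg, *simulate.generate_multistudy_counts(cfg)


def make_bundle(counts, study_id="s", control=None, replicate_group=None, **meta_cols):
    """StudyBundle from a plain counts array/frame with minimal metadata."""
    if not isinstance(counts, pd.DataFrame):
        counts = np.asarray(counts)
        counts = pd.DataFrame(
            counts,
            index=[f"g{i}" for i in range(counts.shape[0])],
            columns=[f"smp{j}" for j in range(counts.shape[1])],
        )
    n = counts.shape[1]
    meta = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "study_id": study_id,
            "control": control if control is not None else [True] * n,
            "replicate_group": replicate_group if replicate_group is not None else list(counts.columns),
            **meta_cols,
        }
    ).set_index("sample_id", drop=False)
    return StudyBundle(study_id=study_id, counts=counts, metadata=meta)
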