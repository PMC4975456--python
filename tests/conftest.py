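import numpy as np
import pandas as pd
import pytest

import thyrotype as tt


@pytest.fixture(scope="session")
def small_cohort():
    """30 tumors + 10 normals, 1200 genes, default planted programs."""
    cfg = tt.CohortConfig(n_tumors=30, n_normals=10, n_genes=1200, seed=7)
    counts, ann, meta, truth = tt.generate_cohort(cfg)
    return cfg, counts, ann, meta, truth


@pytest.fixture()
def tiny_matrix():
    """3 genes x 2 samples count matrix with hand-checkable values."""
    df = pd.DataFrame(
        [[0, 1], [1, 3], [3, 6]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2"],
        dtype=float,
    )
    return tt.ExpressionMatrix(df, unit="counts")


@pytest.fixture()
def tiny_annotation():
    return pd.DataFrame(
        {
            "chromosome": ["chr1", "chr1", "chr2"],
            "start": [0, 200_000, 50_000_000],
            "end": [1000, 201_000, 50_002_000],
            "strand": ["+", "-", "+"],
            "biotype": ["protein_coding"] * 3,
            "length": [1000, 1000, 2000],
            "arm": ["1p", "1p", "2q"],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )


def nb_matrix(rng, mu):
    """Negative-binomial counts (dispersion 0.05) at the given mean matrix."""
    n = 1 / 0.05
    return rng.negative_binomial(n, n / (n + mu)).astype(float)
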