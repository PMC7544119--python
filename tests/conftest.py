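import numpy as np
import pandas as pd
import pytest

import txatlas as tx


@pytest.fixture(scope="session")
def small_sim():
    """Compact compendium: 4 cell types x 4 platforms, 600 genes, 128 samples."""
    cfg = tx.SimConfig(
        n_genes=600,
        n_celltypes=4,
        samples_per_dataset_per_celltype=4,
        frac_marker_genes_per_celltype=0.08,
        seed=101,
    )
    return tx.simulate(cfg)


@pytest.fixture(scope="session")
def small_pct(small_sim):
    expr, annot, truth = small_sim
    return tx.rank_percentile(expr)


@pytest.fixture(scope="session")
def small_atlas(small_sim, small_pct):
    _, annot, _ = small_sim
    return tx.fit_atlas(small_pct, annot, tx.BuildConfig(threshold=0.2, n_components=10))


@pytest.fixture
def tiny_expr():
    vals = pd.DataFrame(
        {"s1": [3.0, 7.0, 1.0], "s2": [2.0, 2.0, 9.0], "s3": [1.0, 4.0, 2.0]},
        index=["g1", "g2", "g3"],
    )
    return tx.ExpressionMatrix(vals, "raw")


@pytest.fixture
def two_platform_annot():
    return tx.SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
                "dataset_id": ["dsA", "dsA", "dsA", "dsB", "dsB", "dsB"],
                "platform": ["P1", "P1", "P1", "P2", "P2", "P2"],
                "cell_type": ["t", "t", "t", "t", "t", "t"],
            }
        )
    )
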