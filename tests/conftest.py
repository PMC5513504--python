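import numpy as np
import pandas as pd
import pytest

import burstnoise as bn


@pytest.fixture
def small_matrix():
    """3 genes x 4 cells, 2 embryos."""
    values = pd.DataFrame(
        {
            "c1": [1.0, 2.0, 0.0],
            "c2": [2.0, 4.0, 1.0],
            "c3": [3.0, 3.0, 2.0],
            "c4": [4.0, 3.0, 3.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    group = pd.Series(["E1", "E1", "E2", "E2"], index=["c1", "c2", "c3", "c4"])
    return bn.ExpressionMatrix(values, group)


@pytest.fixture
def worked_example_matrix():
    """Three embryos of two cells each: [2,4], [3,3], [1,5] for one gene."""
    values = pd.DataFrame(
        [[2.0, 4.0, 3.0, 3.0, 1.0, 5.0]],
        index=pd.Index(["g1"], name="gene_id"),
        columns=[f"c{i}" for i in range(6)],
    )
    group = pd.Series(
        ["E1", "E1", "E2", "E2", "E3", "E3"], index=[f"c{i}" for i in range(6)]
    )
    return bn.ExpressionMatrix(values, group)


@pytest.fixture
def annotation():
    table = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "tss": [10_000, 500, 8_000],
            "tes": [15_000, 100, 3_000],
            "strand": ["+", "-", "-"],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return bn.GeneAnnotation(table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
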