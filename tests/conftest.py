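import numpy as np
import pandas as pd
import pytest

from amygdex.genesets import GeneSet
from amygdex.human_expression import DevExpressionMatrix
from amygdex.simulate import SimConfig, gen_snuc_dataset, gene_names


@pytest.fixture
def small_config():
    return SimConfig(seed=42, n_genes=20, n_clusters=2, n_cells_per_donor=50)


@pytest.fixture
def gene_namespace():
    return gene_names(20)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, two periods, one donor pair per period."""
    values = pd.DataFrame(
        {
            "s1": [5.0, 7.0, 0.0],
            "s2": [7.0, 7.0, 0.0],
            "s3": [9.0, 5.0, 0.0],
            "s4": [5.0, 5.0, 0.0],
        },
        index=["GA", "GB", "GC"],
    )
    meta = pd.DataFrame(
        {
            "region": ["AMY"] * 4,
            "period": [3, 3, 4, 4],
            "hemisphere": ["L", "L", "L", "L"],
            "donor": ["d1", "d2", "d3", "d4"],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return DevExpressionMatrix(values=values, sample_meta=meta)


@pytest.fixture(scope="session")
def null_snuc():
    """Small null dataset reused by several DE tests."""
    config = SimConfig(seed=123, n_genes=30, n_clusters=1, n_cells_per_donor=100)
    return gen_snuc_dataset(config)


def make_gene_set(*symbols, name="test"):
    return GeneSet(name=name, symbols=frozenset(symbols))
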