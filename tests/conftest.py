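import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernanet import (
    ExpressionMatrix,
    GeneratorConfig,
    TargetSiteTable,
    build_backbone,
    filter_expressed,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Small but structurally complete synthetic dataset."""
    cfg = GeneratorConfig(
        n_genes=200,
        n_mirnas=36,
        n_blocks=6,
        samples_per_group=(30, 30, 12, 12),
        n_3us_genes=20,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_backbone(small_dataset):
    kept = filter_expressed(small_dataset.all_expression()).genes
    return build_backbone(small_dataset.targets.restrict_genes(kept))


@pytest.fixture()
def toy_table():
    counts = pd.DataFrame(
        [[2, 0, 1], [0, 0, 0], [1, 1, 0]],
        index=["g1", "g2", "g3"],
        columns=["m1", "m2", "m3"],
    )
    return TargetSiteTable(counts)


def expression_from_array(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


@pytest.fixture()
def path3():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g
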