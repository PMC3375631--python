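import numpy as np
import pandas as pd
import pytest

from pathweight.containers import (
    ExpressionDataset,
    GeneSet,
    PathwayCollection,
    PathwayGraph,
    RankedList,
)


@pytest.fixture
def p6_graph() -> PathwayGraph:
    """Six-node path graph g1-g2-g3-g4-g5-g6."""
    edges = [(f"g{i}", f"g{i + 1}") for i in range(1, 6)]
    return PathwayGraph.from_edges("P6", edges)


@pytest.fixture
def p6_clustered() -> dict:
    """Binary DE profile with the first three path nodes flagged."""
    return {f"g{i}": (1.0 if i in (1, 2, 3) else 0.0) for i in range(1, 7)}


@pytest.fixture
def p6_dispersed() -> dict:
    """Binary DE profile with alternating path nodes flagged."""
    return {f"g{i}": (1.0 if i in (1, 3, 5) else 0.0) for i in range(1, 7)}


@pytest.fixture
def small_collection() -> PathwayCollection:
    return PathwayCollection((
        GeneSet("P1", "first", frozenset({"A", "B", "C"})),
        GeneSet("P2", "second", frozenset({"B", "C", "D"})),
        GeneSet("P3", "third", frozenset({"E", "F"})),
    ))


@pytest.fixture
def four_gene_ranked() -> RankedList:
    return RankedList(["g1", "g2", "g3", "g4"], [3.0, 2.0, 1.0, 0.5])


def make_dataset(
    n_genes: int = 20,
    n_per: int = 4,
    seed: int = 0,
    shifted: dict | None = None,
) -> ExpressionDataset:
    """Small two-class dataset; `shifted` maps gene index -> case-class
    mean shift."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(2 * n_per)]
    values = rng.standard_normal((n_genes, 2 * n_per))
    for gi, shift in (shifted or {}).items():
        values[gi, :n_per] += shift
    labels = pd.Series(["case"] * n_per + ["ctrl"] * n_per, index=samples)
    frame = pd.DataFrame(values, index=genes, columns=samples)
    frame.index.name = "gene_id"
    return ExpressionDataset(frame, labels)


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    return make_dataset()
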