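"""Shared fixtures: small hand-built graphs and datasets with known structure."""

import numpy as np
import pandas as pd
import pytest

from pathwire.graph_model import (GENE, MIRNA, Config, ExpressionDataset,
                                  PathwayGraph)


@pytest.fixture
def toy_graph():
    """5-gene DAG: A->B->C, A->C (triangle) plus D->E branch from C."""
    g = PathwayGraph("toy")
    for n in "ABCDE":
        g.add_node(n, GENE)
    g.add_edge("A", "B", "activation")
    g.add_edge("B", "C", "activation")
    g.add_edge("A", "C", "binding")
    g.add_edge("C", "D", "activation")
    g.add_edge("D", "E", "inhibition")
    return g


@pytest.fixture
def two_group_dataset():
    """6 features x 20 samples, 8 'M' vs 12 'nonM', reproducible."""
    rng = np.random.default_rng(42)
    feats = [f"F{i}" for i in range(6)]
    samples = [f"s{i:02d}" for i in range(20)]
    values = pd.DataFrame(rng.standard_normal((6, 20)), index=feats,
                          columns=samples)
    groups = pd.Series(["M"] * 8 + ["nonM"] * 12, index=samples)
    return ExpressionDataset(values, groups)


@pytest.fixture
def default_config():
    return Config(permutations=99, seed=7)


def random_pathway_graph(rng, n_genes=8, n_mirnas=2, p_edge=0.25):
    """Random typed pathway graph for round-trip / invariance properties."""
    g = PathwayGraph("rand")
    genes = [f"g{i}" for i in range(n_genes)]
    for name in genes:
        g.add_node(name, GENE)
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p_edge:
                rel = rng.choice(["activation", "inhibition", "binding"])
                g.add_edge(genes[i], genes[j], str(rel))
    for m in range(n_mirnas):
        name = f"mir{m}"
        targets = [t for t in genes if rng.random() < 0.4] or [genes[0]]
        g.add_node(name, MIRNA)
        for t in targets:
            g.add_edge(name, t, "mirna-target", provenance="validated")
    return g
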