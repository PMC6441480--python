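import networkx as nx
import numpy as np
import pandas as pd
import pytest

from critnet.expression import ExpressionMatrix


def make_matrix(values, groups=None, genes=None, samples=None) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{i}" for i in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = ["A"] * half + ["B"] * (n_samples - half)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=pd.Series(groups, index=samples),
    )


def random_connected_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi graph resampled until connected (seeded, deterministic)."""
    for attempt in range(100):
        g = nx.gnp_random_graph(n, p, seed=seed * 100 + attempt)
        if g.number_of_nodes() and nx.is_connected(g):
            return g
    raise AssertionError(f"no connected G({n},{p}) found")


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples, log2 scale, 3 + 3 design."""
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(8, 1, size=(4, 6)))
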