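"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators emulate the study design the pipeline targets: a two-group
log2 expression matrix with planted fold changes (a handful of samples per
tumour grade, Gaussian per-entry noise on the log2 scale), a scale-free
interaction network grown by preferential attachment over differentially
expressed plus "added" interactor genes, and random gene-set annotations.
All generators are pure functions of their arguments including the seed.

Defaults mirror the study conditions the pipeline is exercised under:
3 samples per group, planted |log2 fold change| of 3 against per-entry
noise SD 0.5 — a strong microarray signal that a Welch ranking should
recover almost completely.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "ExpressionTruth",
    "AnnotationTable",
    "generate_expression",
    "generate_scale_free_network",
    "generate_annotations",
    "planted_hub_graph",
]


@dataclass(frozen=True)
class ExpressionTruth:
    """Ground truth for a generated expression matrix."""

    planted_genes: frozenset
    log2_effect: float
    sigma: float
    seed: int


@dataclass(frozen=True)
class AnnotationTable:
    """Gene-set annotations: (term_id, term_name, gene set) triples.

    ``universe`` is the background gene set enrichment tests draw from.
    """

    terms: tuple
    universe: frozenset

    def __post_init__(self) -> None:
        seen = set()
        for term_id, _, genes in self.terms:
            if term_id in seen:
                raise ValueError(f"duplicate term id {term_id!r}")
            seen.add(term_id)
            if not genes:
                raise ValueError(f"term {term_id!r} has an empty gene set")
            if not set(genes) <= self.universe:
                raise ValueError(f"term {term_id!r} not a subset of the universe")


def generate_expression(
    n_genes: int = 1000,
    n_per_group: int = 3,
    n_deg: int = 50,
    log2_effect: float = 3.0,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Two-group log2 expression with ``n_deg`` planted fold changes.

    Per-gene baselines are drawn from N(8, 2) on the log2 scale (typical
    microarray intensities); every entry gets independent N(0, sigma) noise.
    The planted effect is added to group B only, so in expectation a planted
    gene's group-mean log2 difference is exactly ``log2_effect`` (and its
    linear fold change is exactly ``2**log2_effect`` when sigma = 0).
    """
    if n_deg > n_genes:
        raise ValueError("n_deg cannot exceed n_genes")
    if n_per_group < 2:
        raise ValueError("need >= 2 samples per group (t-test undefined below)")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"A{j + 1}" for j in range(n_per_group)] + [
        f"B{j + 1}" for j in range(n_per_group)
    ]
    baseline = rng.normal(8.0, 2.0, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, sigma, size=(n_genes, 2 * n_per_group))
    planted_idx = rng.choice(n_genes, size=n_deg, replace=False)
    values[planted_idx, n_per_group:] += log2_effect
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=pd.Series(
            ["A"] * n_per_group + ["B"] * n_per_group, index=samples
        ),
    )
    truth = ExpressionTruth(
        planted_genes=frozenset(genes[i] for i in planted_idx),
        log2_effect=log2_effect,
        sigma=sigma,
        seed=seed,
    )
    return matrix, truth


def generate_scale_free_network(
    n_nodes: int,
    m_edges_per_node: int = 2,
    seed: int = 0,
    node_names: list | None = None,
) -> nx.Graph:
    """Connected scale-free graph grown by preferential attachment.

    Growth starts from a clique of ``m_edges_per_node`` nodes (guaranteeing
    connectivity) and attaches each new node with ``m_edges_per_node`` edges
    preferentially toward high-degree nodes, yielding the heavy-tailed
    degree distribution diagnostic of interaction networks.  ``node_names``
    optionally relabels the nodes (length must equal ``n_nodes``).
    """
    if not 1 <= m_edges_per_node < n_nodes:
        raise ValueError("need 1 <= m_edges_per_node < n_nodes")
    # the seed clique needs at least one edge for attachment to be defined,
    # so m = 1 grows from a 2-clique (a single edge) and still yields a tree
    g = nx.barabasi_albert_graph(
        n_nodes,
        m_edges_per_node,
        seed=int(seed),
        initial_graph=nx.complete_graph(max(m_edges_per_node, 2)),
    )
    if node_names is not None:
        if len(node_names) != n_nodes:
            raise ValueError("node_names length must equal n_nodes")
        g = nx.relabel_nodes(g, dict(enumerate(node_names)))
    return g


def generate_annotations(
    genes: set,
    n_terms: int = 50,
    min_size: int = 5,
    max_size: int = 50,
    seed: int = 0,
) -> AnnotationTable:
    """Random gene-set annotations over ``genes``.

    Term sizes are uniform on [min_size, max_size]; each term's genes are
    drawn without replacement.  The universe is the full supplied gene set.
    """
    if not genes:
        raise ValueError("gene set must be non-empty")
    if not 1 <= min_size <= max_size <= len(genes):
        raise ValueError("need 1 <= min_size <= max_size <= |genes|")
    pool = sorted(str(g) for g in genes)
    rng = np.random.default_rng(seed)
    terms = []
    for i in range(n_terms):
        size = int(rng.integers(min_size, max_size + 1))
        members = frozenset(rng.choice(pool, size=size, replace=False))
        terms.append((f"T{i:03d}", f"synthetic term {i}", members))
    return AnnotationTable(terms=tuple(terms), universe=frozenset(pool))


def planted_hub_graph(
    n_nodes: int = 300,
    m_edges_per_node: int = 2,
    hub_fraction: float = 0.4,
    seed: int = 0,
    hub_name: str = "HUB",
) -> tuple[nx.Graph, str]:
    """Preferential-attachment graph with one planted dominant hub.

    A scale-free graph on ``n_nodes - 1`` nodes is grown first; the planted
    node is then wired to a random ``hub_fraction`` of them, giving it a
    degree (and betweenness/closeness) far above the organic hubs.  Used as
    a benchmark in which the critical-node rules must recover the plant.

    Returns ``(graph, hub_node_id)``.
    """
    if not 0 < hub_fraction <= 1:
        raise ValueError("hub_fraction must be in (0, 1]")
    base = generate_scale_free_network(
        n_nodes - 1,
        m_edges_per_node,
        seed=seed,
        node_names=[f"N{i:04d}" for i in range(n_nodes - 1)],
    )
    rng = np.random.default_rng(seed)
    n_links = max(1, round(hub_fraction * (n_nodes - 1)))
    targets = rng.choice(sorted(base.nodes), size=n_links, replace=False)
    g = base.copy()
    g.add_edges_from((hub_name, t) for t in targets)
    return g, hub_name
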