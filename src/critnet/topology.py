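"""Interaction-network topology: components, centralities, power-law fit.

Graphs are simple and undirected (self-loops dropped, parallel edges
collapsed), matching how a protein-protein interaction network exported from
an interaction database is analysed.  Betweenness centrality is computed with
Brandes' accumulation algorithm on unweighted shortest paths and normalized
by (N-1)(N-2)/2; closeness is the reciprocal of the mean shortest-path
distance, (N-1)/sum(dist).  Both conventions match Cytoscape's
NetworkAnalyzer on a connected component, so the resulting table is directly
comparable with that tool's output.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerLawFit",
    "build_graph",
    "main_component",
    "compute_centralities",
    "degree_distribution",
    "fit_power_law",
]


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of count = a * k^b on log-log axes.

    ``correlation`` is the Pearson r of (log k, log count); ``r_squared`` is
    its square, i.e. the R^2 of the regression on logarithmized values.
    """

    a: float
    b: float
    correlation: float
    r_squared: float
    n_points: int


def build_graph(edges, nodes=None) -> nx.Graph:
    """Build a simple undirected graph from an iterable of node pairs.

    Self-loops are dropped and duplicate/reversed edges collapse.  ``nodes``
    may list additional (possibly isolated) nodes to include.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for i, edge in enumerate(edges, start=1):
        try:
            u, v = edge
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed edge record {i}: {edge!r}") from exc
        if u == v:
            g.add_node(u)
            continue
        g.add_edge(u, v)
    return g


def main_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties on size are broken by the component containing the
    lexicographically smallest node id (compared as strings).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no components")
    components = list(nx.connected_components(g))
    largest = max(len(c) for c in components)
    winner = min(
        (c for c in components if len(c) == largest),
        key=lambda c: min(str(n) for n in c),
    )
    return g.subgraph(winner).copy()


def _bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def _brandes_betweenness(adj: dict) -> dict:
    """Brandes' betweenness accumulation for unweighted graphs.

    Returns raw scores in which every unordered pair is counted twice (once
    from each endpoint as source); callers halve and normalize.
    """
    nodes = list(adj)
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        stack: list = []
        pred: dict = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        dist = dict.fromkeys(nodes, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc


def compute_centralities(g: nx.Graph) -> pd.DataFrame:
    """Degree, normalized betweenness and closeness for a connected graph.

    Returns a DataFrame indexed by node (sorted by node id as string) with
    columns ``degree``, ``betweenness``, ``closeness``.  Input must be
    connected: closeness under the chosen convention is undefined across
    components, so run this on the output of :func:`main_component`.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(g):
        raise ValueError("graph must be connected; extract the main component first")
    nodes = sorted(g.nodes, key=str)
    adj = {v: list(g.neighbors(v)) for v in nodes}
    raw_bc = _brandes_betweenness(adj)
    # raw counts each unordered pair twice; normalizer is (N-1)(N-2)/2
    scale = 1.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    rows = []
    for v in nodes:
        if n > 1:
            total = sum(_bfs_distances(adj, v).values())
            closeness = (n - 1) / total
        else:
            closeness = 0.0
        rows.append(
            {
                "degree": g.degree(v),
                "betweenness": raw_bc[v] * scale,
                "closeness": closeness,
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(nodes, name="node"))
    table["degree"] = table["degree"].astype(int)
    return table


def degree_distribution(g: nx.Graph) -> list[tuple[int, int]]:
    """Observed (degree k, node count) pairs for k >= 1, ascending in k."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    counts: dict[int, int] = {}
    for _, k in g.degree:
        if k >= 1:
            counts[k] = counts.get(k, 0) + 1
    return sorted(counts.items())


def fit_power_law(dist) -> PowerLawFit:
    """Fit count = a * k^b by ordinary least squares on (log k, log count).

    Only points with k >= 1 and count >= 1 enter the fit (log of zero is
    undefined under the model).  Natural logs are used; the base does not
    affect b, the correlation or R^2, and a is recovered via exp.  With two
    points, or when the logged counts are constant, the line interpolates
    the data exactly and both correlation and R^2 are reported as 1.
    """
    pts = [(k, c) for k, c in dist if k >= 1 and c >= 1]
    if len(pts) < 2:
        raise ValueError("need at least 2 points with k >= 1 and count >= 1")
    x = np.log([k for k, _ in pts])
    y = np.log([c for _, c in pts])
    if np.ptp(x) == 0:
        raise ValueError("all degrees identical; slope undefined")
    if np.ptp(y) == 0:
        # horizontal line fits exactly: b = 0, perfect fit by convention
        return PowerLawFit(
            a=float(np.exp(y[0])), b=0.0, correlation=1.0, r_squared=1.0,
            n_points=len(pts),
        )
    fit = stats.linregress(x, y)
    r = float(fit.rvalue)
    r2 = 1.0 if len(pts) == 2 else r * r
    return PowerLawFit(
        a=float(np.exp(fit.intercept)),
        b=float(fit.slope),
        correlation=r,
        r_squared=r2,
        n_points=len(pts),
    )
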