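"""Gene-set term enrichment for small query panels.

A query gene set (here typically the critical nodes of the interaction
network) is tested against each annotated term with the right-tailed
hypergeometric test, adjusted across terms with Holm's step-down procedure.
Enriched terms are grouped by chance-corrected agreement (Cohen's kappa) of
their gene-membership vectors: terms whose kappa reaches a threshold are
linked, and connected components of that graph form the term clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRow",
    "hypergeom_pvalue",
    "enrich",
    "percent_genes_per_term",
    "membership_counts",
    "kappa_score",
    "cluster_terms",
]


@dataclass(frozen=True)
class EnrichmentRow:
    """One enriched term.

    ``percent_gt`` is the percentage of the term's genes found in the query
    (100 * overlap / term size, half-up rounded to 2 decimals), the "% G/T"
    statistic of enrichment tables; ``overlap`` is the "G/T" count.
    """

    term_id: str
    term_name: str
    term_size: int
    overlap: int
    overlap_genes: frozenset
    percent_gt: float
    p_value: float
    adjusted_p: float


def hypergeom_pvalue(k: int, K: int, n: int, U: int) -> float:
    """Right-tailed hypergeometric p-value P(X >= k).

    X counts the overlap between a random size-``n`` draw from a universe of
    ``U`` genes and a fixed term of ``K`` genes.  The survival function is
    evaluated by scipy's hypergeometric distribution, which is numerically
    stable far into the tail.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}")
    if K > U or n > U or K < 0 or n < 0 or U < 1:
        raise ValueError(f"invalid configuration K={K}, n={n}, U={U}")
    return float(stats.hypergeom.sf(k - 1, U, K, n))


def percent_genes_per_term(k: int, K: int) -> float:
    """100 * k / K rounded half-up to two decimals (the %G/T column)."""
    if K < 1:
        raise ValueError("term size K must be >= 1")
    if not 1 <= k <= K:
        raise ValueError("need 1 <= k <= K")
    value = Decimal(100 * k) / Decimal(K)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def enrich(query: set, annotations, alpha: float = 0.05) -> list[EnrichmentRow]:
    """Test a query gene set against every term of an annotation table.

    Query genes outside the table's universe are dropped with a logged
    warning.  Each term overlapping the query in at least one gene gets a
    hypergeometric p-value; Holm step-down adjustment runs across all tested
    terms.  Rows with adjusted p < ``alpha`` are returned, sorted by raw p
    ascending (ties by term id).
    """
    universe = set(annotations.universe)
    effective = set(query) & universe
    dropped = set(query) - effective
    if dropped:
        logger.warning(
            "%d query gene(s) outside the annotation universe dropped: %s",
            len(dropped), sorted(dropped),
        )
    if not effective:
        raise ValueError("no query gene is in the annotation universe")
    U, n = len(universe), len(effective)
    tested = []
    for term_id, term_name, genes in annotations.terms:
        genes = set(genes)
        overlap = effective & genes
        if not overlap:
            continue
        k, K = len(overlap), len(genes)
        tested.append(
            (term_id, term_name, K, k, frozenset(overlap), hypergeom_pvalue(k, K, n, U))
        )
    if not tested:
        return []
    pvals = [t[5] for t in tested]
    adjusted = multipletests(pvals, method="holm")[1]
    rows = [
        EnrichmentRow(
            term_id=term_id,
            term_name=term_name,
            term_size=K,
            overlap=k,
            overlap_genes=overlap,
            percent_gt=percent_genes_per_term(k, K),
            p_value=p,
            adjusted_p=float(adj),
        )
        for (term_id, term_name, K, k, overlap, p), adj in zip(tested, adjusted)
    ]
    rows = [r for r in rows if r.adjusted_p < alpha]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def membership_counts(rows, genes) -> dict:
    """Number of term rows whose gene set contains each queried gene.

    ``rows`` may be :class:`EnrichmentRow` objects or any objects exposing a
    ``genes`` attribute (e.g. the packaged curated term rows, whose gene
    lists are normalized for membership counting).
    """
    counts = {g: 0 for g in genes}
    for row in rows:
        members = getattr(row, "overlap_genes", None)
        if members is None:
            members = row.genes
        for g in genes:
            if g in members:
                counts[g] += 1
    return counts


def kappa_score(term_a: set, term_b: set, universe: set) -> float:
    """Cohen's kappa between two terms' binary membership vectors.

    Over a universe of size U the 2x2 agreement table of the indicator
    vectors gives observed agreement p_o and chance agreement p_e;
    kappa = (p_o - p_e) / (1 - p_e).  When p_e = 1 (both vectors constant
    and identical) kappa is 1 by convention.
    """
    universe = set(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain >= 2 genes")
    a = set(term_a) & universe
    b = set(term_b) & universe
    u = len(universe)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = u - both - only_a - only_b
    p_o = (both + neither) / u
    pa, pb = len(a) / u, len(b) / u
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


def cluster_terms(rows, threshold: float = 0.4, universe: set | None = None) -> dict:
    """Group term rows into clusters by thresholded kappa agreement.

    Builds a graph with an edge between two terms whenever their kappa
    reaches ``threshold``; clusters are the connected components.  Cluster
    ids (1-based) follow the order terms first appear in ``rows`` — with
    rows sorted by p-value, as :func:`enrich` returns them, that is the
    order of the cluster's most significant member.  ``universe`` defaults
    to the union of the rows' gene sets.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    items = []
    for row in rows:
        members = getattr(row, "overlap_genes", None)
        if members is None:
            members = row.genes
        items.append((row.term_id, frozenset(members)))
    if universe is None:
        universe = set().union(*(g for _, g in items)) if items else set()
    g = nx.Graph()
    g.add_nodes_from(term_id for term_id, _ in items)
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if kappa_score(items[i][1], items[j][1], universe) >= threshold:
                g.add_edge(items[i][0], items[j][0])
    assignment: dict = {}
    next_id = 1
    for term_id, _ in items:
        if term_id in assignment:
            continue
        for member in nx.node_connected_component(g, term_id):
            assignment[member] = next_id
        next_id += 1
    return assignment
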