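"""Plain-text readers and writers for every pipeline artifact.

Formats: expression and group labels as TSV, interaction edges as 2-column
TSV or SIF, gene sets as GMT, plus TSV tables for DEGs, centralities and
enrichment and a JSON document for the selection result.  Every writer has
a matching reader so artifacts round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentRow
from .expression import DEGRecord, ExpressionMatrix
from .selection import SelectionResult
from .synthetic import AnnotationTable

__all__ = [
    "write_expression", "read_expression",
    "write_edge_list", "read_edge_list",
    "write_sif", "read_sif",
    "write_gmt", "read_gmt",
    "write_deg_table", "read_deg_table",
    "write_centrality_table", "read_centrality_table",
    "write_selection", "read_selection",
    "write_enrichment_table", "read_enrichment_table",
    "write_clusters", "read_clusters",
]


# -- expression ---------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, expr_path, groups_path) -> None:
    """Expression as TSV (first column ``gene``) plus a sample/group TSV."""
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(expr_path, sep="\t")
    groups = matrix.groups.rename("group")
    groups.index.name = "sample"
    groups.to_csv(groups_path, sep="\t")


def read_expression(expr_path, groups_path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    return ExpressionMatrix(values=values, groups=groups)


# -- graphs -------------------------------------------------------------------

def write_edge_list(g: nx.Graph, path) -> None:
    """Two-column TSV, one edge per line, endpoints sorted for determinism."""
    with open(path, "w") as fh:
        for u, v in sorted((sorted((str(a), str(b))) for a, b in g.edges)):
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(f.strip() for f in fields):
                raise ValueError(f"{path}: malformed edge on line {lineno}: {line!r}")
            edges.append((fields[0].strip(), fields[1].strip()))
    return edges


def write_sif(g: nx.Graph, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v in sorted((sorted((str(a), str(b))) for a, b in g.edges)):
            fh.write(f"{u}\t{relation}\t{v}\n")


def read_sif(path) -> list[tuple[str, str]]:
    """SIF lines are ``source<TAB>relation<TAB>target[<TAB>target...]``."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f for f in line.split("\t") if f.strip()]
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed SIF line {lineno}: {line!r}")
            source = fields[0].strip()
            edges.extend((source, t.strip()) for t in fields[2:])
    return edges


# -- annotations --------------------------------------------------------------

def write_gmt(annotations: AnnotationTable, path) -> None:
    """GMT: term id, description, then tab-separated member genes."""
    with open(path, "w") as fh:
        for term_id, name, genes in annotations.terms:
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def read_gmt(path) -> AnnotationTable:
    """Read GMT; the universe is the union of all term gene sets."""
    terms = []
    universe: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}: {line!r}")
            genes = frozenset(f.strip() for f in fields[2:] if f.strip())
            if not genes:
                raise ValueError(f"{path}: GMT line {lineno} has no genes")
            terms.append((fields[0].strip(), fields[1].strip(), genes))
            universe |= genes
    return AnnotationTable(terms=tuple(terms), universe=frozenset(universe))


# -- tables -------------------------------------------------------------------

def write_deg_table(records: list[DEGRecord], path) -> None:
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "fold_change": [r.fold_change for r in records],
            "p_value": [r.p_value for r in records],
            "rank": [r.rank for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> list[DEGRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DEGRecord(
            gene=str(row.gene),
            fold_change=float(row.fold_change),
            p_value=float(row.p_value),
            rank=int(row.rank),
        )
        for row in df.itertuples()
    ]


def write_centrality_table(table: pd.DataFrame, path) -> None:
    """TSV sorted by degree descending (ties by node id), mirroring how
    hub tables are conventionally printed."""
    out = table.copy()
    out.index = out.index.map(str)
    out.index.name = "node"
    out = out.sort_index(kind="mergesort")
    out = out.sort_values(by=["degree"], ascending=False, kind="mergesort")
    out.to_csv(path, sep="\t")


def read_centrality_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="node")
    table.index = table.index.map(str)
    table["degree"] = table["degree"].astype(int)
    return table


def write_selection(result: SelectionResult, path) -> None:
    payload = {
        name: sorted(map(str, getattr(result, name)))
        for name in ("hubs", "central_bc", "central_cc", "central", "critical")
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_selection(path) -> SelectionResult:
    payload = json.loads(Path(path).read_text())
    return SelectionResult(
        hubs=frozenset(payload["hubs"]),
        central_bc=frozenset(payload["central_bc"]),
        central_cc=frozenset(payload["central_cc"]),
        central=frozenset(payload["central"]),
        critical=frozenset(payload["critical"]),
    )


def write_enrichment_table(rows: list[EnrichmentRow], path) -> None:
    df = pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "term_name": [r.term_name for r in rows],
            "percent_gt": [f"{r.percent_gt:.2f}" for r in rows],
            "n_genes": [r.overlap for r in rows],
            "term_size": [r.term_size for r in rows],
            "genes": [",".join(sorted(r.overlap_genes)) for r in rows],
            "p_value": [r.p_value for r in rows],
            "adjusted_p": [r.adjusted_p for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_enrichment_table(path) -> list[EnrichmentRow]:
    df = pd.read_csv(path, sep="\t")
    return [
        EnrichmentRow(
            term_id=str(row.term_id),
            term_name=str(row.term_name),
            term_size=int(row.term_size),
            overlap=int(row.n_genes),
            overlap_genes=frozenset(str(row.genes).split(",")),
            percent_gt=float(row.percent_gt),
            p_value=float(row.p_value),
            adjusted_p=float(row.adjusted_p),
        )
        for row in df.itertuples()
    ]


def write_clusters(assignment: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tcluster\n")
        for term_id, cluster in sorted(assignment.items(), key=lambda kv: (kv[1], kv[0])):
            fh.write(f"{term_id}\t{cluster}\n")


def read_clusters(path) -> dict:
    assignment = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "term_id\tcluster":
            raise ValueError(f"{path}: unexpected cluster table header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            term_id, cluster = line.rstrip("\n").split("\t")
            assignment[term_id] = int(cluster)
    return assignment
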