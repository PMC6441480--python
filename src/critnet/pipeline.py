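"""End-to-end orchestration: expression -> DEGs -> network -> critical genes -> terms.

``run_pipeline`` executes the full chain — median centering, Welch ranking,
top-N + fold-change DEG filtering, graph construction, main-component
extraction, centralities, power-law fit, hub/central/critical selection,
enrichment of the critical set and kappa clustering of the enriched terms —
writing every intermediate table and a single JSON report.  The run is a
pure function of the config and input files: rerunning yields a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io as cio
from .actions import read_action_edges, summarize_actions
from .enrichment import cluster_terms, enrich
from .expression import (
    boxplot_stats,
    drop_uncharacterized,
    filter_degs,
    median_center,
    rank_genes,
)
from .selection import SelectionConfig, select_nodes
from .topology import (
    build_graph,
    compute_centralities,
    degree_distribution,
    fit_power_law,
    main_component,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one analysis run.

    ``characterized`` optionally points at a one-gene-per-line list; DEGs
    outside it are dropped (by default every gene counts as characterized).
    ``actions`` optionally points at a typed action-edge TSV to summarize.
    """

    expression: Path
    groups: Path
    edges: Path
    annotations: Path
    output_dir: Path
    actions: Path | None = None
    characterized: Path | None = None
    top_n: int = 250
    fc_low: float = 0.5
    fc_high: float = 2.0
    sd_multiplier: float = 2.0
    central_fraction: float = 0.05
    central_mode: str = "intersection"
    alpha: float = 0.05
    kappa_threshold: float = 0.4
    seed: int = 0

    _PATH_FIELDS = ("expression", "groups", "edges", "annotations",
                    "output_dir", "actions", "characterized")

    def __post_init__(self) -> None:
        for name in self._PATH_FIELDS:
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not 0 < self.fc_low <= self.fc_high:
            raise ValueError("need 0 < fc_low <= fc_high")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.kappa_threshold <= 1:
            raise ValueError("kappa_threshold must be in (0, 1]")
        # reuse SelectionConfig's validation of the shared thresholds
        SelectionConfig(self.sd_multiplier, self.central_fraction, self.central_mode)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load a config mapping from YAML; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = Path(path).parent
        for name in cls._PATH_FIELDS:
            if raw.get(name) is not None and not Path(raw[name]).is_absolute():
                raw[name] = base / raw[name]
        return cls(**raw)


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorate


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = _stage("read_expression")(cio.read_expression)(
        config.expression, config.groups
    )
    logger.info("expression: %d genes x %d samples", *matrix.values.shape)

    centered = _stage("median_center")(median_center)(matrix)
    cio.write_expression(centered, out / "expression_centered.tsv", out / "groups.tsv")
    boxplot_stats(centered).to_csv(out / "boxplot_stats.tsv", sep="\t")

    records = _stage("rank_genes")(rank_genes)(centered)
    degs = _stage("filter_degs")(filter_degs)(
        records, top_n=config.top_n, fc_low=config.fc_low, fc_high=config.fc_high
    )
    logger.info("DEG filter: %d ranked -> %d pass top-%d + fold-change",
                len(records), len(degs), config.top_n)
    if config.characterized is not None:
        characterized = {
            line.strip()
            for line in Path(config.characterized).read_text().splitlines()
            if line.strip()
        }
        n_before = len(degs)
        degs = drop_uncharacterized(degs, characterized)
        logger.info("characterized filter: %d -> %d", n_before, len(degs))
    cio.write_deg_table(degs, out / "degs.tsv")

    edge_pairs = _stage("read_edges")(
        cio.read_sif if str(config.edges).endswith(".sif") else cio.read_edge_list
    )(config.edges)
    graph = _stage("build_graph")(build_graph)(edge_pairs)
    component = _stage("main_component")(main_component)(graph)
    logger.info(
        "network: %d nodes / %d edges; main component %d nodes / %d edges",
        graph.number_of_nodes(), graph.number_of_edges(),
        component.number_of_nodes(), component.number_of_edges(),
    )
    cio.write_edge_list(component, out / "main_component_edges.tsv")

    table = _stage("compute_centralities")(compute_centralities)(component)
    cio.write_centrality_table(table, out / "centralities.tsv")
    dist = degree_distribution(component)
    fit = _stage("fit_power_law")(fit_power_law)(dist)

    sel_config = SelectionConfig(
        sd_multiplier=config.sd_multiplier,
        central_fraction=config.central_fraction,
        central_mode=config.central_mode,
    )
    selection = _stage("select_nodes")(select_nodes)(table, sel_config)
    cio.write_selection(selection, out / "selection.json")
    critical_table = table.loc[sorted(selection.critical, key=str)]
    cio.write_centrality_table(critical_table, out / "critical_nodes.tsv")
    logger.info(
        "selection: %d hubs, %d central (BC %d, CC %d), %d critical",
        len(selection.hubs), len(selection.central),
        len(selection.central_bc), len(selection.central_cc),
        len(selection.critical),
    )

    annotations = _stage("read_annotations")(cio.read_gmt)(config.annotations)
    rows: list = []
    clusters: dict = {}
    if not selection.critical:
        logger.warning("critical set is empty; skipping enrichment")
    else:
        query = set(map(str, selection.critical))
        if query & set(annotations.universe):
            rows = _stage("enrich")(enrich)(query, annotations, alpha=config.alpha)
            clusters = _stage("cluster_terms")(cluster_terms)(
                rows, threshold=config.kappa_threshold
            )
        else:
            logger.warning("no critical gene is annotated; skipping enrichment")
    cio.write_enrichment_table(rows, out / "enrichment.tsv")
    cio.write_clusters(clusters, out / "term_clusters.tsv")
    logger.info("enrichment: %d significant terms in %d cluster(s)",
                len(rows), len(set(clusters.values())))

    action_summary: dict = {}
    if config.actions is not None:
        edges = _stage("read_action_edges")(read_action_edges)(config.actions)
        action_summary = summarize_actions(edges)

    report = {
        "parameters": {
            "top_n": config.top_n,
            "fc_low": config.fc_low,
            "fc_high": config.fc_high,
            "sd_multiplier": config.sd_multiplier,
            "central_fraction": config.central_fraction,
            "central_mode": config.central_mode,
            "alpha": config.alpha,
            "kappa_threshold": config.kappa_threshold,
            "seed": config.seed,
        },
        "expression": {
            "n_genes": int(matrix.values.shape[0]),
            "n_samples": int(matrix.values.shape[1]),
        },
        "degs": {
            "n_ranked": len(records),
            "n_selected": len(degs),
            "genes": sorted(r.gene for r in degs),
        },
        "network": {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_isolated": sum(1 for _, d in graph.degree if d == 0),
            "component_nodes": component.number_of_nodes(),
            "component_edges": component.number_of_edges(),
        },
        "power_law": {
            "a": fit.a,
            "b": fit.b,
            "correlation": fit.correlation,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
        },
        "selection": {
            name: sorted(map(str, getattr(selection, name)))
            for name in ("hubs", "central_bc", "central_cc", "central", "critical")
        },
        "enrichment": [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "term_size": r.term_size,
                "overlap": r.overlap,
                "genes": sorted(r.overlap_genes),
                "percent_gt": r.percent_gt,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "cluster": clusters.get(r.term_id),
            }
            for r in rows
        ],
        "actions": action_summary,
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
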