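"""Packaged curated enrichment table for the colon-cancer critical gene panel.

The six-gene panel {MAPK3, AKT1, SRC, TP53, GAPDH, ALB} — hubs that are also
central in the grade II/III colon-cancer interaction network — is annotated
to 34 biological terms drawn from the November 2017 releases of KEGG
(rows 1-16), REACTOME (row 17), WikiPathways (rows 18-33) and the GO
biological-process annotation (row 34).

Each row carries the term name, the percentage of the term's genes found in
the panel (%G/T), the overlap count (G/T) and the associated genes exactly
as published, including one typographical variant: row 1 lists "APK3",
which is MAPK3 (the published per-gene term counts only balance under that
reading).  ``genes_raw`` preserves the printed spelling; ``genes`` is the
normalized set used for membership counting.  The term's total annotated
size is recovered from the printed %G/T (the smallest integer reproducing
it), since the underlying database releases are not shipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["TermRow", "colon_grade_terms", "CRITICAL_PANEL"]

CRITICAL_PANEL = frozenset({"MAPK3", "AKT1", "SRC", "TP53", "GAPDH", "ALB"})

_TYPO_MAP = {"APK3": "MAPK3"}

# (rank, term name, %G/T, G/T, printed associated genes, source)
_ROWS = [
    (1, "HIF-1 signaling pathway", 3.00, 3, ("AKT1", "GAPDH", "APK3"), "KEGG"),
    (2, "ErbB signaling pathway", 3.49, 3, ("AKT1", "MAPK3", "SRC"), "KEGG"),
    (3, "VEGF signaling pathway", 5.08, 3, ("AKT1", "MAPK3", "SRC"), "KEGG"),
    (4, "Estrogen signaling pathway", 3.06, 3, ("AKT1", "MAPK3", "SRC"), "KEGG"),
    (5, "Prolactin signaling pathway", 4.29, 3, ("AKT1", "MAPK3", "SRC"), "KEGG"),
    (6, "Thyroid hormone signaling pathway", 3.45, 4,
     ("AKT1", "MAPK3", "SRC", "TP53"), "KEGG"),
    (7, "Colorectal cancer", 4.17, 3, ("AKT1", "MAPK3", "TP53"), "KEGG"),
    (8, "Pancreatic cancer", 4.00, 3, ("AKT1", "MAPK3", "TP53"), "KEGG"),
    (9, "Endometrial cancer", 5.17, 3, ("AKT1", "MAPK3", "TP53"), "KEGG"),
    (10, "Glioma", 4.23, 3, ("AKT1", "MAPK3", "TP53"), "KEGG"),
    (11, "Prostate cancer", 3.09, 3, ("AKT1", "MAPK3", "TP53"), "KEGG"),
    (12, "Melanoma", 3.95, 3, ("AKT1", "MAPK3", "TP53"), "KEGG"),
    (13, "Bladder cancer", 7.32, 3, ("MAPK3", "SRC", "TP53"), "KEGG"),
    (14, "Chronic myeloid leukemia", 3.85, 3, ("AKT1", "MAPK3", "TP53"), "KEGG"),
    (15, "Non-small cell lung cancer", 4.55, 3, ("AKT1", "MAPK3", "TP53"), "KEGG"),
    (16, "Central carbon metabolism in cancer", 4.62, 3,
     ("AKT1", "MAPK3", "TP53"), "KEGG"),
    (17, "PI5P, PP2A and IER3 Regulate PI3K/AKT Signaling", 3.19, 3,
     ("AKT1", "MAPK3", "SRC"), "REACTOME"),
    (18, "RANKL/RANK (Receptor activator of NFKB (ligand)) Signaling Pathway",
     5.45, 3, ("AKT1", "MAPK3", "SRC"), "WikiPathways"),
    (19, "Human Thyroid Stimulating Hormone (TSH) signaling pathway", 4.55, 3,
     ("AKT1", "MAPK3", "SRC"), "WikiPathways"),
    (20, "Leptin signaling pathway", 3.95, 3, ("AKT1", "MAPK3", "SRC"),
     "WikiPathways"),
    (21, "Follicle Stimulating Hormone (18) signaling pathway", 11.11, 3,
     ("AKT1", "MAPK3", "SRC"), "WikiPathways"),
    (22, "Prolactin Signaling Pathway", 3.95, 3, ("AKT1", "MAPK3", "SRC"),
     "WikiPathways"),
    (23, "Signaling Pathways in Glioblastoma", 4.82, 4,
     ("AKT1", "MAPK3", "SRC", "TP53"), "WikiPathways"),
    (24, "AGE/RAGE pathway", 4.55, 3, ("AKT1", "MAPK3", "SRC"), "WikiPathways"),
    (25, "Interleukin-11 Signaling Pathway", 6.82, 3, ("AKT1", "MAPK3", "SRC"),
     "WikiPathways"),
    (26, "Oncostatin M Signaling Pathway", 6.15, 4,
     ("AKT1", "MAPK3", "SRC", "TP53"), "WikiPathways"),
    (27, "Alpha 6 Beta 4 signaling pathway", 9.09, 3, ("AKT1", "MAPK3", "SRC"),
     "WikiPathways"),
    (28, "IL-3 Signaling Pathway", 6.12, 3, ("AKT1", "MAPK3", "SRC"),
     "WikiPathways"),
    (29, "Kit receptor signaling pathway", 5.08, 3, ("AKT1", "MAPK3", "SRC"),
     "WikiPathways"),
    (30, "Rac1/Pak1/p38/MMP-2 pathway", 5.97, 4,
     ("AKT1", "MAPK3", "SRC", "TP53"), "WikiPathways"),
    (31, "Hepatitis C and Hepatocellular Carcinoma", 5.88, 3,
     ("AKT1", "MAPK3", "TP53"), "WikiPathways"),
    (32, "Endometrial cancer", 5.17, 3, ("AKT1", "MAPK3", "TP53"),
     "WikiPathways"),
    (33, "EPO Receptor Signaling", 11.54, 3, ("AKT1", "MAPK3", "SRC"),
     "WikiPathways"),
    (34, "regulation of telomerase activity", 5.88, 3, ("MAPK3", "SRC", "TP53"),
     "GO_BiologicalProcess"),
]


@dataclass(frozen=True)
class TermRow:
    """One curated enrichment row."""

    term_id: str
    rank: int
    name: str
    percent_gt: float
    n_genes: int
    genes_raw: tuple
    genes: frozenset
    source: str
    term_size: int


def _infer_term_size(percent_gt: float, k: int) -> int:
    """Smallest term size K whose half-up rounded 100*k/K matches %G/T."""
    target = Decimal(str(percent_gt)).quantize(Decimal("0.01"))
    best = round(100 * k / percent_gt)
    for cand in (best, best - 1, best + 1):
        if cand < k:
            continue
        got = (Decimal(100 * k) / Decimal(cand)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
        if got == target:
            return cand
    raise ValueError(f"no integer term size reproduces %G/T={percent_gt} at k={k}")


def colon_grade_terms() -> tuple[list[TermRow], frozenset]:
    """The 34 curated term rows and the six-gene critical panel query.

    Returns ``(rows, query)`` where each row keeps the printed gene spelling
    in ``genes_raw`` and the normalized set in ``genes``.
    """
    rows = []
    for rank, name, pct, k, genes_raw, source in _ROWS:
        normalized = frozenset(_TYPO_MAP.get(g, g) for g in genes_raw)
        rows.append(
            TermRow(
                term_id=f"R{rank:02d}",
                rank=rank,
                name=name,
                percent_gt=pct,
                n_genes=k,
                genes_raw=tuple(genes_raw),
                genes=normalized,
                source=source,
                term_size=_infer_term_size(pct, k),
            )
        )
    return rows, CRITICAL_PANEL
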