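"""Hub, central and critical node selection on a centrality table.

Hubs are nodes whose degree reaches mean + c*SD of the degree distribution
(sample SD, c = 2 by default).  Central nodes are the top 5% of the network
by betweenness and by closeness centrality; the two top lists are combined
by intersection (default, the stricter reading) or union.  Critical nodes
are the hubs that are also central — the candidate biomarker panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "select_hubs",
    "select_top_fraction",
    "critical_nodes",
    "select_nodes",
]

_METRICS = ("betweenness", "closeness")


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for hub/central selection.

    sd_multiplier
        Number of degree standard deviations above the mean a hub must
        reach (>= 0).
    central_fraction
        Fraction of nodes, per centrality metric, called central (in (0, 1]).
    central_mode
        How the betweenness-top and closeness-top sets combine into the
        central set: ``"intersection"`` (default) or ``"union"``.
    """

    sd_multiplier: float = 2.0
    central_fraction: float = 0.05
    central_mode: str = "intersection"

    def __post_init__(self) -> None:
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")
        if not 0 < self.central_fraction <= 1:
            raise ValueError("central_fraction must be in (0, 1]")
        if self.central_mode not in ("intersection", "union"):
            raise ValueError("central_mode must be 'intersection' or 'union'")


@dataclass(frozen=True)
class SelectionResult:
    """Named node sets produced by the selection rules.

    Invariants: ``central`` combines ``central_bc`` and ``central_cc`` per
    the configured mode and ``critical = hubs & central``.
    """

    hubs: frozenset
    central_bc: frozenset
    central_cc: frozenset
    central: frozenset
    critical: frozenset


def select_hubs(table: pd.DataFrame, config: SelectionConfig = SelectionConfig()) -> set:
    """Nodes with degree >= mean + sd_multiplier * sample SD of degree.

    The threshold is inclusive, so when all degrees are equal (SD = 0) every
    node meets the cutoff.  Requires >= 2 nodes (sample SD needs them).
    """
    if len(table) < 2:
        raise ValueError("need >= 2 nodes to form a degree SD")
    deg = table["degree"]
    cutoff = deg.mean() + config.sd_multiplier * deg.std(ddof=1)
    return set(table.index[deg >= cutoff])


def select_top_fraction(
    table: pd.DataFrame,
    metric: str,
    config: SelectionConfig = SelectionConfig(),
) -> set:
    """Top ceil(fraction * N) nodes by a centrality metric.

    Ties are broken by degree descending then node id lexicographically, so
    exactly ceil(fraction * N) nodes are returned deterministically.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {_METRICS}")
    if len(table) < 1:
        raise ValueError("empty centrality table")
    n_select = math.ceil(config.central_fraction * len(table))
    order = sorted(
        table.index,
        key=lambda v: (-table.at[v, metric], -table.at[v, "degree"], str(v)),
    )
    return set(order[:n_select])


def critical_nodes(
    hubs: set, central_bc: set, central_cc: set, central_mode: str = "intersection"
) -> set:
    """Hubs that are also central under the chosen combination mode."""
    if central_mode == "intersection":
        central = set(central_bc) & set(central_cc)
    elif central_mode == "union":
        central = set(central_bc) | set(central_cc)
    else:
        raise ValueError("central_mode must be 'intersection' or 'union'")
    return set(hubs) & central


def select_nodes(
    table: pd.DataFrame, config: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """Apply all three selection rules to a centrality table."""
    hubs = select_hubs(table, config)
    bc = select_top_fraction(table, "betweenness", config)
    cc = select_top_fraction(table, "closeness", config)
    if config.central_mode == "intersection":
        central = bc & cc
    else:
        central = bc | cc
    return SelectionResult(
        hubs=frozenset(hubs),
        central_bc=frozenset(bc),
        central_cc=frozenset(cc),
        central=frozenset(central),
        critical=frozenset(hubs & central),
    )
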