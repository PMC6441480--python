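"""Typed action edges among genes: activation, inhibition, binding, expression.

An action map is user-supplied curated data (a textual stand-in for the
coloured action networks interaction browsers draw): directed edges for
activation, inhibition and expression, undirected edges for binding.
"""

from __future__ import annotations

from dataclasses import dataclass

ACTIONS = ("activation", "inhibition", "binding", "expression")

__all__ = ["ActionEdge", "read_action_edges", "write_action_edges", "summarize_actions"]

_HEADER = "source\ttarget\taction\tdirected"


@dataclass(frozen=True)
class ActionEdge:
    """One typed interaction; binding edges must be undirected."""

    source: str
    target: str
    action: str
    directed: bool

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}; expected one of {ACTIONS}")
        if self.action == "binding" and self.directed:
            raise ValueError("binding edges are undirected")


def _parse_bool(token: str, path, lineno: int) -> bool:
    lowered = token.strip().lower()
    if lowered in ("true", "1", "yes"):
        return True
    if lowered in ("false", "0", "no"):
        return False
    raise ValueError(f"{path}: line {lineno}: bad directed flag {token!r}")


def read_action_edges(path) -> list[ActionEdge]:
    """Read a 4-column TSV (source, target, action, directed).

    A literal header line is allowed and skipped.  Unknown action keywords
    raise with the offending line number.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line.strip() == _HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields, got {len(fields)}")
            source, target, action, directed = (f.strip() for f in fields)
            try:
                edges.append(
                    ActionEdge(
                        source=source,
                        target=target,
                        action=action,
                        directed=_parse_bool(directed, path, lineno),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return edges


def write_action_edges(edges: list[ActionEdge], path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for e in edges:
            fh.write(f"{e.source}\t{e.target}\t{e.action}\t{str(e.directed).lower()}\n")


def summarize_actions(edges: list[ActionEdge]) -> dict:
    """Per-node counts of incoming/outgoing directed actions and undirected ones.

    Directed edges count once under the source's ``out`` and once under the
    target's ``in``; undirected edges count once under each endpoint's
    ``undirected`` bucket.  Total outgoing counts equal the number of
    directed edges.
    """
    summary: dict = {}

    def bucket(node: str) -> dict:
        return summary.setdefault(node, {"in": {}, "out": {}, "undirected": {}})

    for e in edges:
        if e.directed:
            out = bucket(e.source)["out"]
            out[e.action] = out.get(e.action, 0) + 1
            inc = bucket(e.target)["in"]
            inc[e.action] = inc.get(e.action, 0) + 1
        else:
            for node in (e.source, e.target):
                und = bucket(node)["undirected"]
                und[e.action] = und.get(e.action, 0) + 1
    return summary
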