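"""Regulator-level hierarchy and network topology.

The regulator-regulator edge set generally contains cycles; a greedy
heuristic keeps the most significant edges first and rejects any edge
that would close a directed cycle, yielding a DAG. Levels are shortest
path distances from root regulators (no incoming kept edge); the removed
edges can be reintroduced and classified by the level jump they span.
The module also provides transitive reduction, exact 2/3-node
feedback/feed-forward motif counts, degree distributions, weakly
connected components and hub-removal robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DagLayout",
    "MotifCounts",
    "greedy_dag",
    "assign_levels",
    "transitive_reduction",
    "classify_edges",
    "count_motifs",
    "hub_robustness",
    "degree_distributions",
]


@dataclass
class DagLayout:
    kept: pd.DataFrame  # columns a, b, pp
    removed: pd.DataFrame
    levels: dict[str, int] = field(default_factory=dict)


@dataclass
class MotifCounts:
    two_node_feedback: int
    three_node_feedback: int
    feedforward: int


def greedy_dag(edges: pd.DataFrame) -> DagLayout:
    """Greedy acyclicity heuristic.

    Edges are processed in decreasing posterior probability (ties broken
    lexicographically by (source, target)); an edge is kept unless it
    closes a directed cycle with the already-kept edges.
    """
    if edges.empty:
        return DagLayout(kept=edges.copy(), removed=edges.copy())
    ordered = edges.sort_values(by=["pp", "a", "b"], ascending=[False, True, True], kind="mergesort")
    g = nx.DiGraph()
    g.add_nodes_from(pd.unique(edges[["a", "b"]].values.ravel()))
    kept_rows, removed_rows = [], []
    for row in ordered.itertuples(index=False):
        u, v = row.a, row.b
        if g.has_node(v) and g.has_node(u) and nx.has_path(g, v, u):
            removed_rows.append(row)
        else:
            g.add_edge(u, v)
            kept_rows.append(row)
    kept = pd.DataFrame(kept_rows, columns=ordered.columns).reset_index(drop=True)
    removed = pd.DataFrame(removed_rows, columns=ordered.columns).reset_index(drop=True)
    layout = DagLayout(kept=kept, removed=removed)
    layout.levels = assign_levels(kept, nodes=list(g.nodes))
    return layout


def _digraph(edges: pd.DataFrame, nodes=None) -> nx.DiGraph:
    g = nx.DiGraph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    if not edges.empty:
        g.add_edges_from(zip(edges["a"], edges["b"]))
    return g


def assign_levels(dag_edges: pd.DataFrame, nodes=None) -> dict[str, int]:
    """Shortest-path level per node: roots (no incoming edge) at 0.

    Isolated nodes are roots. Raises on cyclic input.
    """
    g = _digraph(dag_edges, nodes)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("input edges contain a directed cycle")
    roots = [v for v in g.nodes if g.in_degree(v) == 0]
    levels = nx.multi_source_dijkstra_path_length(g, roots) if roots else {}
    return {v: int(levels.get(v, 0)) for v in g.nodes}


def transitive_reduction(dag_edges: pd.DataFrame) -> pd.DataFrame:
    """Unique minimal edge set of a DAG preserving all reachability."""
    g = _digraph(dag_edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("transitive reduction requires an acyclic input")
    reduced = nx.transitive_reduction(g)
    keep = set(reduced.edges)
    mask = [
        (a, b) in keep for a, b in zip(dag_edges["a"], dag_edges["b"])
    ]
    return dag_edges[mask].reset_index(drop=True)


EDGE_CLASSES = ("same-level", "one-below", "one-above", "two-or-more-above", "long-forward")


def classify_edges(edges: pd.DataFrame, levels: dict[str, int]) -> pd.Series:
    """Class per edge from the level jump level(target) - level(source).

    0 -> same-level, +1 -> one-below, -1 -> one-above, <= -2 ->
    two-or-more-above; jumps >= +2 are reported as a distinct
    "long-forward" class.
    """

    def cls(a: str, b: str) -> str:
        d = levels[b] - levels[a]
        if d == 0:
            return "same-level"
        if d == 1:
            return "one-below"
        if d == -1:
            return "one-above"
        if d <= -2:
            return "two-or-more-above"
        return "long-forward"

    return pd.Series([cls(a, b) for a, b in zip(edges["a"], edges["b"])], index=edges.index)


def count_motifs(edges: pd.DataFrame) -> MotifCounts:
    """Exact 2/3-node feedback and feed-forward loop counts by enumeration.

    feedforward counts ordered triples (x->y, y->z, x->z) with distinct
    nodes; three_node_feedback counts directed 3-cycles once per node set;
    two_node_feedback counts reciprocal pairs once.
    """
    eset = set(zip(edges["a"], edges["b"]))
    succ: dict[str, set[str]] = {}
    for a, b in eset:
        succ.setdefault(a, set()).add(b)
    fb2 = sum(1 for (a, b) in eset if a < b and (b, a) in eset)
    ff = 0
    cyc3_ordered = 0
    for x, ys in succ.items():
        for y in ys:
            if y == x:
                continue
            for z in succ.get(y, ()):
                if z == x or z == y:
                    continue
                if (x, z) in eset:
                    ff += 1
                if (z, x) in eset:
                    cyc3_ordered += 1
    return MotifCounts(
        two_node_feedback=fb2,
        three_node_feedback=cyc3_ordered // 3,
        feedforward=ff,
    )


def hub_robustness(edges: pd.DataFrame, k_max: int = 10) -> pd.DataFrame:
    """Relative largest weakly-connected-component size after hub removal.

    Hubs are ranked by out-degree (ties broken lexicographically); for
    each k = 1..k_max the top-k hubs and their incident edges are deleted
    and the largest weakly connected component is reported relative to the
    original node count.
    """
    if edges.empty:
        raise ValueError("hub robustness needs a nonempty network")
    g = _digraph(edges)
    n0 = g.number_of_nodes()
    hubs = sorted(g.nodes, key=lambda v: (-g.out_degree(v), v))
    rows = []
    for k in range(1, min(k_max, n0) + 1):
        h = g.copy()
        h.remove_nodes_from(hubs[:k])
        largest = max((len(c) for c in nx.weakly_connected_components(h)), default=0)
        rows.append({"k": k, "removed": hubs[k - 1], "relative_lcc": largest / n0})
    return pd.DataFrame(rows)


def degree_distributions(edges: pd.DataFrame) -> pd.DataFrame:
    """Per-node in/out degree table (all zeros for an empty edge set)."""
    g = _digraph(edges)
    return pd.DataFrame(
        {
            "node": list(g.nodes),
            "out_degree": [g.out_degree(v) for v in g.nodes],
            "in_degree": [g.in_degree(v) for v in g.nodes],
        }
    ).sort_values("node").reset_index(drop=True)
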