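"""Co-authorship network construction and analysis.

Authors are nodes; an edge joins two authors with weight equal to the number
of publications they co-authored.  The module provides weighted degree,
node/edge betweenness (shortest paths on the unweighted topology by default,
with a weighted-distance mode), connected components, and divisive
community detection by iterative removal of the highest-betweenness edge
(Girvan–Newman), stopping at the partition of maximal weighted modularity
encountered along the removal sequence.

Determinism: among equally central edges the lexicographically smallest
(by sorted endpoint keys) is removed first, and component ids are ordered by
their smallest member key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import networkx as nx

from .records import BiblioRecord, CorpusError

__all__ = [
    "build_coauthor_graph", "degree_centrality", "betweenness_centrality",
    "components", "girvan_newman_partition", "CommunityPartition",
    "export_graph", "import_graph", "graph_stats", "plot_graph",
]


def build_coauthor_graph(records: Sequence[BiblioRecord],
                         assignment: dict[tuple[str, int], int] | None = None,
                         node_labels: dict[Hashable, str] | None = None
                         ) -> nx.Graph:
    """Weighted co-publication graph over canonical authors.

    Each record with k authors adds +1 weight to each of its C(k,2) author
    pairs; a single-author record contributes an isolated node.  When an
    ``assignment`` (from :func:`fundingaudit.names.cluster_records`) is
    given, nodes are canonical cluster indices; otherwise nodes are folded
    full name keys.  ``node_labels`` attaches a ``status`` attribute
    (e.g. on-list vs unlisted vs subsidiary-only) for export colouring.
    """
    from .names import normalize_name

    g = nx.Graph()
    for rec in records:
        if not rec.authors:
            raise CorpusError(f"record {rec.record_id} has no authors")
        if assignment is not None:
            nodes = sorted({assignment[(rec.record_id, i)]
                            for i in range(len(rec.authors))})
        else:
            nodes = sorted({normalize_name(a).full_folded for a in rec.authors})
        for n in nodes:
            if n not in g:
                g.add_node(n)
        for u, v in combinations(nodes, 2):
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    if node_labels:
        for n, lab in node_labels.items():
            if n in g:
                g.nodes[n]["status"] = lab
    return g


def degree_centrality(graph: nx.Graph) -> dict[Hashable, float]:
    """Weighted degree: the sum of each node's incident edge weights."""
    return {n: float(d) for n, d in graph.degree(weight="weight")}


def betweenness_centrality(graph: nx.Graph, target: str = "nodes",
                           weighted: bool = False) -> dict:
    """Unnormalized betweenness with fractional shortest-path attribution.

    ``target`` selects node scores (endpoints excluded) or edge scores.
    By default shortest paths ignore edge weights (the co-publication count
    is a tie strength, not a distance); ``weighted=True`` uses 1/weight as
    the distance so heavily collaborating pairs are "closer".
    """
    g = graph
    weight_attr = None
    if weighted:
        g = graph.copy()
        for u, v, d in g.edges(data=True):
            d["dist"] = 1.0 / d.get("weight", 1)
        weight_attr = "dist"
    if target == "nodes":
        return nx.betweenness_centrality(g, normalized=False, weight=weight_attr)
    if target == "edges":
        return nx.edge_betweenness_centrality(g, normalized=False,
                                              weight=weight_attr)
    raise CorpusError(f"unknown betweenness target {target!r}")


def components(graph: nx.Graph) -> dict[Hashable, int]:
    """Connected-component labels, ids ordered by smallest member key."""
    comps = [sorted(c, key=_node_sort_key) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: _node_sort_key(c[0]))
    return {n: i for i, comp in enumerate(comps) for n in comp}


def _node_sort_key(n: Hashable):
    return (0, n) if isinstance(n, (int, float)) else (1, str(n))


def _edge_key(u, v) -> tuple:
    a, b = sorted((u, v), key=_node_sort_key)
    return (_node_sort_key(a), _node_sort_key(b))


@dataclass
class CommunityPartition:
    """Node→community assignment with quality and the edge-removal trace."""

    assignment: dict[Hashable, int]
    quality: float
    removal_sequence: list[tuple[Hashable, Hashable]] = field(default_factory=list)

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for n, c in self.assignment.items():
            out.setdefault(c, set()).add(n)
        return [out[c] for c in sorted(out)]


def _partition_of_components(graph: nx.Graph) -> dict[Hashable, int]:
    return components(graph)


def _modularity(original: nx.Graph, assignment: dict[Hashable, int]) -> float:
    comms: dict[int, set] = {}
    for n, c in assignment.items():
        comms.setdefault(c, set()).add(n)
    return float(nx.algorithms.community.modularity(
        original, comms.values(), weight="weight"))


def girvan_newman_partition(graph: nx.Graph, stop: str = "max_modularity",
                            k_components: int | None = None,
                            weighted: bool = False) -> CommunityPartition:
    """Divisive edge-betweenness community detection.

    Iteratively removes the highest-betweenness edge (recomputing after
    every removal) and tracks the component structure.  Under
    ``stop="max_modularity"`` the full removal sequence is walked and the
    partition with maximal weighted modularity on the *original* graph is
    returned (the initial component structure is a candidate, so the quality
    is never below 0).  Under ``stop="k_components"`` removal halts as soon
    as the graph splits into at least ``k_components`` parts.

    An edgeless graph yields the singleton partition with quality 0.
    """
    if graph.number_of_edges() == 0:
        return CommunityPartition(
            {n: i for i, n in enumerate(sorted(graph.nodes, key=_node_sort_key))},
            0.0, [])
    if stop not in ("max_modularity", "k_components"):
        raise CorpusError(f"unknown stopping rule {stop!r}")
    if stop == "k_components" and (k_components is None or k_components < 1):
        raise CorpusError("k_components stopping rule needs k_components >= 1")

    work = graph.copy()
    removal: list[tuple[Hashable, Hashable]] = []
    best_assign = _partition_of_components(work)
    best_q = _modularity(graph, best_assign)
    while work.number_of_edges() > 0:
        if stop == "k_components":
            if nx.number_connected_components(work) >= k_components:
                break
        eb = betweenness_centrality(work, target="edges", weighted=weighted)
        max_b = max(eb.values())
        tol = 1e-9 * max(1.0, abs(max_b))
        candidates = [e for e, b in eb.items() if b >= max_b - tol]
        u, v = min((tuple(sorted(e, key=_node_sort_key)) for e in candidates),
                   key=lambda e: _edge_key(*e))
        work.remove_edge(u, v)
        removal.append((u, v))
        if stop == "max_modularity":
            assign = _partition_of_components(work)
            q = _modularity(graph, assign)
            if q > best_q + 1e-12:
                best_q, best_assign = q, assign
    if stop == "k_components":
        best_assign = _partition_of_components(work)
        best_q = _modularity(graph, best_assign)
    return CommunityPartition(best_assign, best_q, removal)


def graph_stats(graph: nx.Graph) -> dict[str, float]:
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "total_edge_weight": float(sum(d.get("weight", 1)
                                       for _, _, d in graph.edges(data=True))),
        "n_components": nx.number_connected_components(graph)
        if graph.number_of_nodes() else 0,
    }


def export_graph(graph: nx.Graph, path: str | Path,
                 partition: CommunityPartition | None = None,
                 fmt: str = "graphml") -> None:
    """Write the attributed graph as GraphML or a TSV edge list.

    Node attributes carried: ``status`` colour class (if set), weighted
    degree, and community id when a partition is given; edges carry weights.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes}, copy=True)
    deg = degree_centrality(graph)
    for n in graph.nodes:
        g.nodes[str(n)]["degree"] = float(deg[n])
        if partition is not None:
            g.nodes[str(n)]["community"] = int(partition.assignment[n])
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d.get('weight', 1)}\n")
    else:
        raise CorpusError(f"unknown export format {fmt!r}")


def import_graph(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(Path(path))
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, weight=int(d.get("weight", 1)))
    return out


def plot_graph(graph: nx.Graph, path: str | Path,
               partition: CommunityPartition | None = None,
               seed: int = 0) -> None:
    """Basic spring-layout rendering (diagnostic aid, not a figure engine)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(graph, seed=seed)
    deg = degree_centrality(graph)
    sizes = [20 + 10 * deg[n] for n in graph.nodes]
    colors = None
    if partition is not None:
        colors = [partition.assignment[n] for n in graph.nodes]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(graph, pos=pos, ax=ax, node_size=sizes,
                     node_color=colors, with_labels=False,
                     edge_color="#999999", cmap="tab20")
    ax.set_axis_off()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
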