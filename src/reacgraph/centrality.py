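"""Directed centrality metrics: clustering, betweenness, bridging.

For a node *i* with neighbor set Λ(i) (union of in- and out-neighbors)
of size k_i:

* clustering coefficient  C(i) = n_i / (k_i (k_i − 1)), where n_i counts
  the directed arcs among the neighbors of i;
* betweenness centrality  B(i) = Σ_{j≠i≠k} σ_jk(i) / σ_jk over ordered
  pairs with σ_jk > 0, unnormalized, on directed unweighted shortest
  paths;
* bridging coefficient    Br(i) = degree_total(i)^(-1) /
  Σ_{j∈Λ(i)} degree_total(j)^(-1).  In a directed network a node can
  only relay flow if it has both incoming and outgoing arcs, so the
  *gated* form returns 0 whenever degree_in(i) = 0 or degree_out(i) = 0;
* bridging centrality     BrC(i) = B(i) × Br_gated(i): high values mark
  low-degree connectors sitting between highly connected modules.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "clustering_coefficient",
    "betweenness_centrality",
    "bridging_coefficient",
    "bridging_centrality",
    "centrality_table",
]


def _neighbors(graph: nx.DiGraph, node) -> set:
    if node not in graph:
        raise KeyError(node)
    nbrs = set(graph.predecessors(node)) | set(graph.successors(node))
    nbrs.discard(node)
    return nbrs


def clustering_coefficient(
    graph: nx.DiGraph, node, singleton_convention: str = "zero"
) -> float:
    """Directed clustering C(i) = n_i / (k_i (k_i - 1)).

    With fewer than two neighbors the formula is 0/0; the configured
    convention value (0 by default) is returned instead.
    """
    if singleton_convention not in {"zero", "one"}:
        raise ValueError(f"unknown singleton convention {singleton_convention!r}")
    nbrs = _neighbors(graph, node)
    k = len(nbrs)
    if k < 2:
        return 0.0 if singleton_convention == "zero" else 1.0
    n_arcs = sum(1 for u in nbrs for v in graph.successors(u) if v in nbrs and v != u)
    return n_arcs / (k * (k - 1))


def betweenness_centrality(graph: nx.DiGraph) -> dict:
    """Unnormalized directed betweenness over ordered endpoint pairs."""
    return nx.betweenness_centrality(graph, normalized=False)


def bridging_coefficient(graph: nx.DiGraph, node, gated: bool = True) -> float:
    """Bridging coefficient of ``node``; gated form is the directed default.

    A neighbor reachable both ways is counted once in the denominator.
    Nodes with no neighbors return 0.
    """
    nbrs = _neighbors(graph, node)
    if not nbrs:
        return 0.0
    if gated and (graph.in_degree(node) == 0 or graph.out_degree(node) == 0):
        return 0.0
    d_total = graph.in_degree(node) + graph.out_degree(node)
    denom = sum(1.0 / (graph.in_degree(j) + graph.out_degree(j)) for j in nbrs)
    return (1.0 / d_total) / denom


def bridging_centrality(graph: nx.DiGraph) -> dict:
    """BrC(i) = B(i) x gated bridging coefficient, for every node."""
    btw = betweenness_centrality(graph)
    return {n: btw[n] * bridging_coefficient(graph, n, gated=True) for n in graph.nodes}


def centrality_table(
    graph: nx.DiGraph,
    gated_bridging: bool = True,
    singleton_convention: str = "zero",
) -> pd.DataFrame:
    """Per-node metric table in lexicographic node order.

    Columns: node, degree_in, degree_out, degree_total, clustering,
    betweenness, bridging_coeff, bridging_centrality.  The bridging
    centrality column always uses the gated coefficient; the
    ``bridging_coeff`` column follows ``gated_bridging``.
    """
    btw = betweenness_centrality(graph)
    rows = []
    for n in sorted(graph.nodes):
        d_in, d_out = graph.in_degree(n), graph.out_degree(n)
        rows.append(
            {
                "node": n,
                "degree_in": d_in,
                "degree_out": d_out,
                "degree_total": d_in + d_out,
                "clustering": clustering_coefficient(graph, n, singleton_convention),
                "betweenness": btw[n],
                "bridging_coeff": bridging_coefficient(graph, n, gated=gated_bridging),
                "bridging_centrality": btw[n]
                * bridging_coefficient(graph, n, gated=True),
            }
        )
    columns = [
        "node", "degree_in", "degree_out", "degree_total",
        "clustering", "betweenness", "bridging_coeff", "bridging_centrality",
    ]
    return pd.DataFrame(rows, columns=columns)
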