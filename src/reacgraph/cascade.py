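"""Cascade sets and cascade numbers in directed networks.

When a node fails, every downstream node that loses *all* of its inputs
fails in turn, and the loss propagates to a fixpoint.  The *cascade set*
of a node is the set of nodes that cease to receive information when it
fails; the *cascade number* is the size of that set.  Source nodes
(in-degree 0) never starve — they have no inputs to lose — and a node
inside a directed cycle survives as long as any live input still feeds
the cycle.

A node contained in no other node's cascade set is a *leading cascade
node* and its cascade set is *independent*: it is not absorbed into any
larger cascade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "CascadeResult",
    "cascade_set",
    "all_cascades",
    "leading_cascade_nodes",
    "classify_cascade_subnetwork",
]


@dataclass
class CascadeResult:
    node: str
    cascade_set: frozenset[str]
    independent: bool = False
    subnetwork_type: str = "empty"

    @property
    def cascade_number(self) -> int:
        return len(self.cascade_set)


def cascade_set(graph: nx.DiGraph, node) -> frozenset:
    """Nodes starved of all input when ``node`` fails (seed excluded).

    Worklist fixpoint: maintain, for every node, the count of in-neighbors
    not yet failed; a node with positive in-degree fails when that count
    reaches zero.  The fixpoint is order-independent, so the result is
    deterministic.  O(|V| + |A|) per seed.
    """
    if node not in graph:
        raise KeyError(node)
    alive_in = {u: graph.in_degree(u) for u in graph.nodes}
    failed = {node}
    stack = [node]
    while stack:
        u = stack.pop()
        for v in graph.successors(u):
            if v in failed:
                continue
            alive_in[v] -= 1
            if alive_in[v] == 0 and graph.in_degree(v) > 0:
                failed.add(v)
                stack.append(v)
    failed.discard(node)
    return frozenset(failed)


def all_cascades(graph: nx.DiGraph) -> dict[str, CascadeResult]:
    """Cascade result for every node, with independence and subnetwork type."""
    results = {
        n: CascadeResult(node=n, cascade_set=cascade_set(graph, n))
        for n in graph.nodes
    }
    leading = leading_cascade_nodes(graph, results)
    for n, res in results.items():
        res.independent = n in leading
        res.subnetwork_type = classify_cascade_subnetwork(graph, res)
    return results


def leading_cascade_nodes(
    graph: nx.DiGraph, results: dict[str, CascadeResult] | None = None
) -> set:
    """Nodes not contained in any other node's cascade set.

    Also verifies the absorption rule (v in cascade(w) implies
    cascade(v) a subset of cascade(w)); mutual membership between two
    would-be leaders is reported as non-independent with a warning.
    """
    if results is None:
        results = {
            n: CascadeResult(node=n, cascade_set=cascade_set(graph, n))
            for n in graph.nodes
        }
    absorbed = set()
    mutual = set()
    for w, res in results.items():
        for v in res.cascade_set:
            absorbed.add(v)
            if w in results[v].cascade_set:
                mutual.add(v)
                continue  # mutual membership: containment holds only modulo seeds
            if not results[v].cascade_set <= res.cascade_set:
                raise AssertionError(
                    f"absorption violated: {v!r} in cascade({w!r}) but "
                    f"cascade({v!r}) not contained in it"
                )
    if mutual:
        warnings.warn(
            f"mutual cascade membership among {sorted(mutual)}; "
            "all reported as non-independent"
        )
    return set(graph.nodes) - absorbed


def classify_cascade_subnetwork(graph: nx.DiGraph, result: CascadeResult) -> str:
    """Type of the subgraph induced on the seed and its cascade set.

    ``empty`` for cascade number 0; ``tree`` when the induced subgraph is
    an arborescence rooted at the seed (each member one in-arc, seed
    none, weakly connected); ``linear_path`` when additionally no node
    branches (out-degree <= 1); ``other`` otherwise.
    """
    if not result.cascade_set:
        return "empty"
    members = set(result.cascade_set) | {result.node}
    H = graph.subgraph(members)
    seed_ok = H.in_degree(result.node) == 0
    members_ok = all(H.in_degree(v) == 1 for v in result.cascade_set)
    connected = nx.is_weakly_connected(H)
    if seed_ok and members_ok and connected:
        if all(H.out_degree(v) <= 1 for v in members):
            return "linear_path"
        return "tree"
    return "other"
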