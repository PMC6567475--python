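"""Global topology: degree distributions, power-law fits, modularity,
degree-preserving randomization and the modularity null test.

The null model keeps every node's in- and out-degree fixed while
shuffling who connects to whom (double-arc swaps), so an observed
modularity far above the null distribution reflects genuine modular
organisation rather than the degree sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "DegreeDistribution",
    "NullModelSummary",
    "degree_distribution",
    "fit_power_law",
    "modularity",
    "detect_communities",
    "randomize_degree_preserving",
    "modularity_null_test",
]


@dataclass
class DegreeDistribution:
    """Empirical P(k) of one degree kind over a graph's nodes."""

    kind: str  # in | out | total
    support: tuple[int, ...]  # strictly increasing, may include k = 0
    probability: tuple[float, ...]

    def __post_init__(self):
        if any(p < 0 for p in self.probability):
            raise ValueError("negative probability")
        if list(self.support) != sorted(set(self.support)):
            raise ValueError("support must be strictly increasing")


@dataclass
class NullModelSummary:
    observed_modularity: float
    null_mean: float
    null_sd: float
    replicates: int
    empirical_p: float


def degree_distribution(graph: nx.DiGraph, kind: str = "total") -> DegreeDistribution:
    """P(k) = (#nodes of degree k) / |V|.  k = 0 is kept in the output
    but excluded from log-log fitting downstream."""
    if graph.number_of_nodes() == 0:
        raise ValueError("degree distribution of an empty graph is undefined")
    if kind == "in":
        degs = [d for _, d in graph.in_degree()]
    elif kind == "out":
        degs = [d for _, d in graph.out_degree()]
    elif kind == "total":
        degs = [graph.in_degree(n) + graph.out_degree(n) for n in graph.nodes]
    else:
        raise ValueError(f"unknown degree kind {kind!r}")
    n = len(degs)
    counts: dict[int, int] = {}
    for d in degs:
        counts[d] = counts.get(d, 0) + 1
    support = tuple(sorted(counts))
    prob = tuple(counts[k] / n for k in support)
    return DegreeDistribution(kind=kind, support=support, probability=prob)


def fit_power_law(
    dist: DegreeDistribution, method: str = "loglog_ls"
) -> tuple[float, float]:
    """Estimate the exponent of P(k) ~ k**gamma.

    ``loglog_ls`` (default): least-squares slope of log P(k) vs log k over
    the support points with k >= 1 and P(k) > 0; returns (gamma, r_squared),
    gamma negative for a decaying distribution.  ``mle``: the continuous
    approximation to the discrete maximum-likelihood exponent,
    alpha = 1 + n / sum(ln(k / (k_min - 1/2))) with k_min = 1, weighted by
    P(k); returned on the same (negative) sign convention, with the log-log
    r_squared as diagnostic.  The MLE form is a diagnostic only: at
    k_min = 1 the continuous approximation is known to be biased on
    discrete data.
    """
    pts = [
        (k, p)
        for k, p in zip(dist.support, dist.probability)
        if k >= 1 and p > 0
    ]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 support points with k >= 1, got {len(pts)}")
    logk = np.log10([k for k, _ in pts])
    logp = np.log10([p for _, p in pts])
    slope, intercept = np.polyfit(logk, logp, 1)
    resid = logp - (slope * logk + intercept)
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if method == "loglog_ls":
        return float(slope), r2
    if method == "mle":
        w = np.array([p for _, p in pts])
        k = np.array([k for k, _ in pts], dtype=float)
        k_min = k.min()
        alpha = 1.0 + w.sum() / float(np.sum(w * np.log(k / (k_min - 0.5))))
        return -alpha, r2
    raise ValueError(f"unknown method {method!r}")


def modularity(graph: nx.DiGraph, partition: dict) -> float:
    """Directed Newman modularity Q of a node -> community map.

    Q = (1/m) sum_within A_uv  -  sum_c Kout_c * Kin_c / m^2,
    where Kout_c/Kin_c are the community's total out-/in-degrees.
    """
    missing = set(graph.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition misses nodes {sorted(missing)[:5]}")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    within = sum(1 for u, v in graph.edges if partition[u] == partition[v])
    kout: dict = {}
    kin: dict = {}
    for n in graph.nodes:
        c = partition[n]
        kout[c] = kout.get(c, 0) + graph.out_degree(n)
        kin[c] = kin.get(c, 0) + graph.in_degree(n)
    expected = sum(kout[c] * kin[c] for c in kout) / (m * m)
    return within / m - expected


def detect_communities(
    graph: nx.DiGraph, method: str = "greedy", seed: int = 0
) -> dict:
    """Heuristic directed-modularity partition, node -> community id.

    ``greedy``: agglomerative merging of the community pair with the
    largest directed-Q gain until no merge improves Q.  ``leiden``: the
    Leiden algorithm (python-igraph / leidenalg) with directed
    modularity, deterministic given ``seed``.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return {}
    if method == "leiden":
        return _leiden_partition(graph, nodes, seed)
    if method != "greedy":
        raise ValueError(f"unknown method {method!r}")

    m = graph.number_of_edges()
    if m == 0:
        return {n: i for i, n in enumerate(nodes)}

    comm = {n: i for i, n in enumerate(nodes)}
    members: dict[int, set] = {i: {n} for i, n in enumerate(nodes)}
    kout = {i: graph.out_degree(n) for i, n in enumerate(nodes)}
    kin = {i: graph.in_degree(n) for i, n in enumerate(nodes)}
    # arcs between communities, both directions pooled
    e: dict[tuple[int, int], int] = {}
    for u, v in graph.edges:
        a, b = comm[u], comm[v]
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        e[key] = e.get(key, 0) + 1

    while True:
        best_gain, best_pair = 0.0, None
        for (a, b), arcs in e.items():
            gain = arcs / m - (kout[a] * kin[b] + kout[b] * kin[a]) / (m * m)
            if gain > best_gain + 1e-12 or (
                best_pair is not None
                and abs(gain - best_gain) <= 1e-12
                and (a, b) < best_pair
            ):
                if gain > 1e-12:
                    best_gain, best_pair = gain, (a, b)
        if best_pair is None:
            break
        a, b = best_pair  # merge b into a
        members[a] |= members.pop(b)
        kout[a] += kout.pop(b)
        kin[a] += kin.pop(b)
        new_e: dict[tuple[int, int], int] = {}
        for (x, y), arcs in e.items():
            x = a if x == b else x
            y = a if y == b else y
            if x == y:
                continue
            key = (x, y) if x < y else (y, x)
            new_e[key] = new_e.get(key, 0) + arcs
        e = new_e

    out = {}
    for new_id, (_, mem) in enumerate(sorted(members.items())):
        for n in mem:
            out[n] = new_id
    return out


def _leiden_partition(graph: nx.DiGraph, nodes: list, seed: int) -> dict:
    import igraph
    import leidenalg

    index = {n: i for i, n in enumerate(nodes)}
    g = igraph.Graph(
        n=len(nodes),
        edges=[(index[u], index[v]) for u, v in graph.edges],
        directed=True,
    )
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition, seed=seed
    )
    return {n: part.membership[index[n]] for n in nodes}


def randomize_degree_preserving(
    graph: nx.DiGraph, n_swaps: int | None = None, seed: int = 0
) -> nx.DiGraph:
    """Degree-preserving randomization by double-arc swaps.

    Repeatedly rewires (u->v, x->y) into (u->y, x->v), rejecting swaps
    that would create self-arcs or parallel arcs, so both degree
    sequences are preserved exactly.  Default target is 10 x |A|
    accepted swaps; if no legal swap exists the graph is returned as a
    copy with a warning.  Arc metabolite annotations travel with the
    source endpoint and are not biologically meaningful afterwards.
    """
    rng = np.random.default_rng(seed)
    out = graph.copy()
    arcs = sorted(out.edges)
    if len(arcs) < 2:
        warnings.warn("fewer than 2 arcs; nothing to randomize")
        return out
    if n_swaps is None:
        n_swaps = 10 * len(arcs)
    accepted = 0
    attempts = 0
    max_attempts = max(100 * n_swaps, 1000)
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(arcs), size=2)
        if i == j:
            continue
        (u, v), (x, y) = arcs[i], arcs[j]
        if u == x or v == y:  # swap would be a no-op
            continue
        if u == y or x == v:  # swap would create a self-arc
            continue
        if out.has_edge(u, y) or out.has_edge(x, v):  # parallel arc
            continue
        data_uv = out.edges[u, v]
        data_xy = out.edges[x, y]
        out.remove_edge(u, v)
        out.remove_edge(x, y)
        out.add_edge(u, y, **data_uv)
        out.add_edge(x, v, **data_xy)
        arcs[i], arcs[j] = (u, y), (x, v)
        accepted += 1
    if accepted == 0:
        warnings.warn("no legal degree-preserving swap found; returning copy")
    return out


def modularity_null_test(
    graph: nx.DiGraph,
    replicates: int = 1000,
    seed: int = 0,
    method: str = "greedy",
) -> NullModelSummary:
    """Observed modularity vs degree-matched random networks.

    Communities are re-detected on every randomized replicate; the
    empirical p-value uses the add-one estimator
    (1 + #{null >= observed}) / (1 + replicates), so it is never
    exactly zero.
    """
    observed = modularity(graph, detect_communities(graph, method=method, seed=seed))
    rng = np.random.default_rng(seed)
    null = np.empty(replicates)
    in_seq = sorted(d for _, d in graph.in_degree())
    out_seq = sorted(d for _, d in graph.out_degree())
    for r in range(replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rand = randomize_degree_preserving(graph, seed=rep_seed)
        assert sorted(d for _, d in rand.in_degree()) == in_seq
        assert sorted(d for _, d in rand.out_degree()) == out_seq
        null[r] = modularity(
            rand, detect_communities(rand, method=method, seed=rep_seed)
        )
    p = (1 + int(np.sum(null >= observed))) / (1 + replicates)
    return NullModelSummary(
        observed_modularity=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if replicates > 1 else 0.0,
        replicates=replicates,
        empirical_p=p,
    )
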