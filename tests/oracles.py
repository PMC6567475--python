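"""Independently coded brute-force oracles used only by the tests.

These deliberately avoid the code paths (and the networkx algorithms)
used by the package: betweenness is computed by exhaustive DFS path
enumeration, cascades by delete-and-strip simulation, modularity by
literal arc counting over ordered node pairs, and the hypergeometric
tail by enumeration over binomial coefficients.
"""

from math import comb


def all_paths(succ: dict, source, target, max_len: int):
    """All simple paths source->target up to max_len arcs (DFS)."""
    out = []

    def walk(path):
        head = path[-1]
        if head == target and len(path) > 1:
            out.append(list(path))
            return
        if len(path) - 1 >= max_len:
            return
        for nxt in succ.get(head, ()):
            if nxt not in path:
                path.append(nxt)
                walk(path)
                path.pop()

    walk([source])
    return out


def brute_betweenness(nodes, arcs) -> dict:
    """B(i) over ordered pairs by exhaustive shortest-path enumeration."""
    succ: dict = {}
    for u, v in arcs:
        succ.setdefault(u, []).append(v)
    nodes = list(nodes)
    btw = {n: 0.0 for n in nodes}
    for j in nodes:
        for k in nodes:
            if j == k:
                continue
            paths = all_paths(succ, j, k, max_len=len(nodes))
            if not paths:
                continue
            d = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == d]
            sigma = len(shortest)
            for i in nodes:
                if i in (j, k):
                    continue
                through = sum(1 for p in shortest if i in p[1:-1])
                btw[i] += through / sigma
    return btw


def brute_clustering(nodes, arcs, node) -> float:
    nbrs = {v for u, v in arcs if u == node} | {u for u, v in arcs if v == node}
    nbrs.discard(node)
    k = len(nbrs)
    if k < 2:
        return 0.0
    n_i = sum(1 for u, v in arcs if u in nbrs and v in nbrs and u != v)
    return n_i / (k * (k - 1))


def brute_bridging_coefficient(nodes, arcs, node, gated=True) -> float:
    def deg(n):
        d_in = sum(1 for u, v in arcs if v == n)
        d_out = sum(1 for u, v in arcs if u == n)
        return d_in, d_out

    nbrs = {v for u, v in arcs if u == node} | {u for u, v in arcs if v == node}
    nbrs.discard(node)
    if not nbrs:
        return 0.0
    d_in, d_out = deg(node)
    if gated and (d_in == 0 or d_out == 0):
        return 0.0
    denom = sum(1.0 / sum(deg(j)) for j in nbrs)
    return (1.0 / (d_in + d_out)) / denom


def brute_cascade_set(nodes, arcs, seed) -> frozenset:
    """Delete the seed, then repeatedly strip nodes with positive original
    in-degree whose surviving in-neighbors are all gone."""
    in_nbrs = {n: set() for n in nodes}
    for u, v in arcs:
        in_nbrs[v].add(u)
    dead = {seed}
    changed = True
    while changed:
        changed = False
        for n in nodes:
            if n in dead or not in_nbrs[n]:
                continue
            if in_nbrs[n] <= dead:
                dead.add(n)
                changed = True
    return frozenset(dead - {seed})


def brute_modularity(nodes, arcs, partition) -> float:
    m = len(arcs)
    if m == 0:
        return 0.0
    arc_set = set(arcs)
    q = 0.0
    for u in nodes:
        for v in nodes:
            if partition[u] != partition[v]:
                continue
            a_uv = 1.0 if (u, v) in arc_set else 0.0
            kout = sum(1 for a, b in arcs if a == u)
            kin = sum(1 for a, b in arcs if b == v)
            q += a_uv / m - kout * kin / (m * m)
    return q


def brute_hypergeom_upper(k, population, n_success, n_draw) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = comb(population, n_draw)
    acc = 0
    for x in range(k, min(n_success, n_draw) + 1):
        if n_draw - x > population - n_success:
            continue
        acc += comb(n_success, x) * comb(population - n_success, n_draw - x)
    return acc / total
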