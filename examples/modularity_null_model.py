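"""Modularity significance against degree-preserving random networks.

Builds a planted two-module digraph (two bidirectional 5-cliques joined
by a single arc), then compares its detected modularity with 100
degree-matched randomizations.  The observed value should sit far above
the null distribution (empirical p at the add-one floor).
"""

import reacgraph as rg

graph = rg.ReactionGraph()
for group in ([f"L{i}" for i in range(5)], [f"R{i}" for i in range(5)]):
    for u in group:
        for v in group:
            if u != v:
                graph.add_arc(u, v, {"m"})
graph.add_arc("L0", "R0", {"m"})

summary = rg.modularity_null_test(graph, replicates=100, seed=17)
print(f"observed modularity : {summary.observed_modularity:.4f}")
print(f"null mean +/- sd    : {summary.null_mean:.4f} +/- {summary.null_sd:.4f}")
print(f"empirical p-value   : {summary.empirical_p:.4f}  ({summary.replicates} replicates)")

print(
    "\nEvery replicate keeps each node's in- and out-degree, so the gap"
    "\nbetween observed and null modularity reflects genuine community"
    "\nstructure, not the degree sequence.  The p-value uses the add-one"
    "\nestimator and can never be exactly zero."
)
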