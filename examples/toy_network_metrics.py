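"""Centrality and cascade metrics on the built-in 7-node demonstration network.

The network is a feed-forward module A->{B,C}->D funnelling through the
path D->E->F into the 2-cycle F<->G.  It illustrates what each metric
sees: D is the bottleneck (highest betweenness), E the bridge (highest
bridging centrality), A the strongest local controller (cascade number 4).
"""

import reacgraph as rg

graph = rg.fig1_toy_graph()
table = rg.centrality_table(graph, gated_bridging=False)
print(table.round(4).to_string(index=False))

print("\ncascade analysis:")
for node, result in sorted(rg.all_cascades(graph).items()):
    members = ",".join(sorted(result.cascade_set)) or "-"
    print(
        f"  {node}: cascade_number={result.cascade_number:d} "
        f"set={{{members}}} independent={result.independent} "
        f"type={result.subnetwork_type}"
    )

print(
    "\nD carries every shortest path between the upstream module and the"
    "\ndownstream chain (betweenness 9); E, a degree-2 node between two"
    "\nhigher-degree neighbors, is the top bridge (bridging centrality 6.86);"
    "\nremoving A starves B, C, D and E, but F survives via the F<->G cycle."
)
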