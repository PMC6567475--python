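"""Essentiality enrichment of highly ranked reactions.

Constructs a synthetic reaction set where essentiality probability rises
with bridging centrality, then computes (a) the essential proportion in
the top 5% with its hypergeometric p-value and (b) the per-cascade-number
essentiality of leading cascade nodes.
"""

import numpy as np
import pandas as pd

import reacgraph as rg

rng = np.random.default_rng(11)
n = 400
nodes = [f"r{i:03d}" for i in range(n)]
score = rng.gamma(shape=1.2, scale=2.0, size=n)
rank = score.argsort().argsort() / n  # 0 = lowest, 1 = highest
labels = {nd: bool(rng.random() < 0.05 + 0.6 * r) for nd, r in zip(nodes, rank)}
table = pd.DataFrame({"node": nodes, "bridging_centrality": score})

report = rg.topk_essential_proportion(table, labels, "bridging_centrality", 0.05)
print(
    f"top 5% by bridging centrality: {report.n_essential_in_top}/{report.n_top} "
    f"essential ({100 * report.proportion_essential:.1f}%), "
    f"hypergeometric p = {report.hypergeometric_p:.2e}"
)

binned = rg.binned_essentiality(table, labels, "bridging_centrality", n_bins=10)
print("\nper-decile essentiality (bin 9 = highest scores):")
print(binned.round(1).to_string(index=False))

print(
    "\nBecause the labels were built to correlate with the metric, the top"
    "\ntier is enriched above the ~35% base rate and the per-decile percent"
    "\ntrends upward; with real flux-balance essentiality labels the same"
    "\ncalls quantify how predictive each centrality is."
)
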