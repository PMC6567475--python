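"""Degree distributions and power-law exponents of a reaction graph.

Genome-scale reaction graphs are scale-free: P(k) ~ k**gamma with gamma
around -1.3 to -1.5.  This example fits the estimator on an exactly
generated power-law distribution (recovering gamma to two decimals) and
then on a synthetic metabolic model's reaction graph.
"""

import numpy as np

import reacgraph as rg

# exact synthetic distribution: the estimator must recover the exponent
support = tuple(range(1, 101))
raw = np.array([k**-1.5 for k in support])
dist = rg.DegreeDistribution("total", support, tuple(raw / raw.sum()))
gamma, r2 = rg.fit_power_law(dist)
print(f"exact P(k) ~ k^-1.5     -> fitted gamma = {gamma:.3f} (r^2 = {r2:.4f})")

# a synthetic metabolic model run through the full pipeline
model = rg.synthetic_model(rg.SyntheticModelSpec(seed=7))
graph = rg.build_reaction_graph(model)
for kind in ("in", "out", "total"):
    d = rg.degree_distribution(graph, kind)
    try:
        g_hat, r2 = rg.fit_power_law(d)
        print(f"synthetic graph {kind:>5}-degree: gamma = {g_hat:.2f} (r^2 = {r2:.2f})")
    except ValueError as exc:
        print(f"synthetic graph {kind:>5}-degree: not fittable ({exc})")

print(
    "\nThe random synthetic model is not scale-free, so its exponents and"
    "\nfit quality are diagnostic only; on genome-scale reaction graphs the"
    "\nlog-log fit reports gamma in the -1.3..-1.5 range."
)
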