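# Methods

## Graph representation

A metabolic model (metabolites with compartments, reactions with signed
stoichiometry and a reversibility flag) is converted into a **simple directed
reaction graph**: nodes are reactions, and an arc u → v exists when some
metabolite producible by u is consumable by v. For an irreversible reaction,
producible = products and consumable = substrates; a reversible reaction can
run either way, so both of its metabolite sets are treated as producible *and*
consumable (direction-union semantics). This keeps reversible reactions as
single nodes — two consecutive reversible reactions sharing a metabolite form
a directed 2-cycle — rather than splitting them into forward/backward copies.
Self-arcs and parallel arcs are excluded; each arc is annotated with the set
of mediating metabolites. Stoichiometric coefficients are stored for
provenance but do not weight arcs: only the presence of a shared metabolite
matters.

Before construction:

1. **Currency metabolites** (ubiquitous cofactors: ATP/ADP/AMP, NAD(P)(H),
   water, protons, phosphate, CO₂, O₂, CoA, quinones, …) are removed from all
   reactions. Paths through such species are biologically meaningless
   shortcuts. The default list (25 compartment-stripped base ids in
   `graph_builder.DEFAULT_CURRENCY_METABOLITES`) is an explicit, versioned
   configuration and fully user-overridable: published node/arc totals for any
   specific genome-scale model are sensitive to this list, and no canonical
   list exists, so exact-count reproduction must be read as
   configuration-dependent.
2. **Exchange reactions** (one empty side, or an EX_/DM_/SK_ id prefix) and
   **transport reactions** (identical compartment-stripped species multisets
   on both sides with at least one compartment change) are dropped. They
   shuttle matter across the cell boundary without transforming it, inflate
   path lengths, and weaken intracellular modularity. All compartments are
   treated uniformly.
3. Reactions left with no non-currency metabolites are dropped entirely;
   reactions that survive filtering but gain no arcs are **kept as isolated
   nodes** (they count toward |V| and carry cascade number 0).

Reversibility when reading SBML: a reaction is reversible if its `reversible`
attribute is true **or** its lower flux bound (FBC parameter or legacy
kinetic-law `LOWER_BOUND`) is negative — model releases encode it both ways.

## Centrality metrics

All metrics operate on the directed graph; Λ(i) is the union of in- and
out-neighbors of node i, k_i = |Λ(i)|, degree_total = in-degree + out-degree
(the graph is simple, so degrees equal neighbor counts and a mutual pair
contributes one to each side).

- **Clustering coefficient** C(i) = n_i / (k_i (k_i − 1)), with n_i the number
  of directed arcs among Λ(i). For k_i ≤ 1 the formula is 0/0; the package
  returns a configurable convention value, default 0 (a node with one
  neighbor shows no evidence of clustering). C ∈ [0, 1]; every node of a
  complete bidirectional digraph has C = 1.
- **Betweenness centrality** B(i) = Σ_{j≠i≠k} σ_jk(i)/σ_jk over *ordered*
  endpoint pairs with σ_jk > 0, on directed unweighted shortest paths,
  **unnormalized** (so values are path counts, e.g. 9, 8, 5 on the 7-node
  demonstration network, not ratios). Computed via Brandes' algorithm
  (networkx, `normalized=False`); the test suite cross-checks it against an
  exhaustive path enumerator on graphs of ≤ 8 nodes.
- **Bridging coefficient** Br(i) = degree_total(i)⁻¹ / Σ_{j∈Λ(i)}
  degree_total(j)⁻¹, each neighbor counted once even when connected both
  ways. In a directed network a node with no incoming or no outgoing arcs
  cannot relay flow, so the directed (**gated**) form returns 0 whenever
  in-degree or out-degree is zero. The raw (ungated) form is exposed as an
  option because reference tabulations report the ungated value for pure
  sources/sinks; the two differ only on such nodes.
- **Bridging centrality** BrC(i) = B(i) × Br_gated(i). High values mark
  low-degree nodes wedged between high-degree neighborhoods — module
  boundaries. Since B = 0 for pure sources and sinks, the gate choice never
  changes BrC.

## Cascade algorithm

The cascade set of a seed node v is the fixpoint of input starvation: start
with F = {v}; repeatedly add any node u ∉ F with positive in-degree whose
in-neighbors all lie in F; stop at the fixpoint and report F \ {v}. Nodes
with in-degree 0 never starve, and a directed cycle survives while any
external live input feeds it. The fixpoint is order-independent, so the
result is deterministic. Implementation: a worklist with a per-node counter
of unfailed in-neighbors — O(|V| + |A|) per seed, O(|V|(|V| + |A|)) for all
nodes. The seed is treated as failed but excluded from its own set and from
the cascade number.

Containment ("absorption") holds in the form: if v ∈ cascade(w) then
cascade(v) ⊆ cascade(w) ∪ {w}. The seed term is necessary — two nodes can be
mutually contained (an isolated 2-cycle is the minimal case), and then
neither set is a subset of the other. A node contained in no other node's
cascade set is a **leading cascade node**; its cascade set is **independent**
(not absorbed by any other). Mutual containment demotes both nodes to
non-leading, with a warning.

Each non-empty cascade set is classified by the subgraph H induced on
{seed} ∪ set: **tree** when H is an arborescence rooted at the seed (seed has
no in-arc in H, every member exactly one, H weakly connected);
**linear_path** when additionally no node of H branches (out-degree ≤ 1);
**other** otherwise. Classification looks only at induced arcs, because the
type describes the cascade subnetwork itself, not the surrounding ancestry.

## Global topology

- **Degree distributions** P(k) = (#nodes of degree k)/|V| for in-, out- and
  total degree; k = 0 is reported but excluded from fitting (log undefined).
- **Power-law exponent**: default estimator is the least-squares slope of
  log P(k) versus log k over the support (reported with r² of the fit); it
  recovers the exponent of exactly generated distributions to ±0.02 and
  matches the convention in which reaction-graph exponents are quoted at
  magnitudes near 1 (γ ≈ −1.3 … −1.5). A continuous-approximation maximum-
  likelihood estimate (α = 1 + n/Σ ln(k/(k_min − ½)), k_min = 1) is available
  as a diagnostic only: at k_min = 1 the continuous approximation is known to
  be biased on discrete support, so its magnitude is not comparable with the
  log-log slope and the tests assert only its sign and ordering.
- **Directed modularity** Q = (1/m) Σ_within A_uv − Σ_c K^out_c K^in_c / m²,
  evaluated exactly from the partition (cross-checked against an arc-counting
  oracle and networkx).
- **Community detection** is heuristic and method-dependent; no single
  optimizer is canonical. Default is a seeded greedy agglomeration on
  directed Q (merge the community pair with the largest positive gain until
  none remains, deterministic tie-break); a Leiden backend
  (igraph/leidenalg, directed, seeded) is available. Published modularity
  values for specific models are therefore treated as method-dependent, not
  as exact targets.
- **Degree-preserving randomization**: repeated double-arc swaps
  (u→v, x→y) ⇒ (u→y, x→v), rejecting self-arcs, parallel arcs and no-ops,
  preserving both degree sequences exactly. Default 10·|A| accepted swaps,
  capped at 100× that many attempts; a graph with no legal swap (e.g. a lone
  2-cycle) is returned unchanged with a warning. Arc metabolite annotations
  travel with the swap and are meaningless afterwards.
- **Modularity null test**: communities are re-detected on each of R
  randomized replicates (degree sequences asserted every time); the
  empirical p-value is (1 + #{Q_null ≥ Q_obs})/(1 + R) — the add-one
  estimator, so p is never exactly 0 and its floor at R = 100 is ≈ 0.0099.

## Essentiality enrichment

Labels are consumed as a `reaction_id → essential/non-essential` table
produced by external constraint-based simulation; coverage below 50% of graph
nodes triggers a warning. Three summaries:

- **Top-k enrichment**: n_top = round(fraction·|V|) (default 5%), metric ties
  broken lexicographically by node id so reports are invariant to input row
  order; significance is the hypergeometric upper tail for the number of
  essentials among the top set (the test the published P-values most
  plausibly correspond to; flagged as a choice, not asserted as identical).
- **Binned essentiality** along a metric (default rank deciles; equal-width
  value bins optional), with per-bin counts conserved and empty bins emitted
  as missing.
- **Cascade summary**: leading cascade nodes binned by cascade number
  0–6 with ≥ 7 pooled; Pearson correlation between bin value (pooled bin
  contributes 7) and percent essential over non-empty bins. Percentages in
  published tables of this kind are truncated (not rounded) to one decimal;
  comparisons in the tests follow that convention.

## Synthetic data generator

`SyntheticModelSpec` emulates the *shape* of a genome-scale model: a random
bipartite stoichiometry over cytosolic metabolites, ~80% of internal
reactions touching a currency cofactor pair, 30% reversible reactions
(typical of curated reconstructions), plus designated exchange (empty product
side, EX_ prefix) and transport (same species, compartment change) reactions
at 10% and 8% of the reaction count. It is deterministic under its seed. It
does **not** emulate mass balance, flux consistency, realistic pathway
topology or scale-free degree structure — so tests passing on it validate
graph-construction logic, filtering, and metric arithmetic, not biological
realism; the demonstration-network regression and the genome-scale checks
carry that weight.

## Problem sizes and numerics

Default verification sizes: oracle equivalence on 200 random digraphs of ≤ 8
nodes (path enumeration) plus 200 of ≤ 50 nodes (cascade strip-down); null
tests at 100 replicates on a 10-node planted two-module graph; power-law
recovery on 100-point exact distributions. These sizes make every
distributional claim in the suite re-computable in seconds while leaving the
algorithms identical at genome scale. Floating-point comparisons against
four-decimal reference values use an absolute tolerance of 5·10⁻⁵; empirical
p-values use the add-one estimator throughout. All randomized procedures
take explicit seeds; outputs are emitted in lexicographic node order so files
are byte-reproducible.

## Known limitations

- Exact node/arc totals for published genome-scale conversions depend on the
  (unpublished) currency list and boundary conventions of the original
  analysis; named-reaction quantities (degrees, cascade sets) are the robust
  reproduction targets.
- The cascade model propagates failure downstream only (input starvation);
  upstream output-loss propagation (bidirectional failure under steady-state
  flux balance) is a different algorithm and out of scope.
- Community detection is a heuristic; two runs with different methods or
  seeds may return different partitions of equal or near-equal Q.
- Flux balance analysis, growth media and objective functions are out of
  scope; essentiality enters only as externally produced labels.
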