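"""Programmatic test inputs: the 7-node demonstration network, random
digraphs, and synthetic metabolic models.

The demonstration network is the one used throughout the package docs:
a feed-forward module A->{B,C}->D funnelling through the path D->E->F
into the 2-cycle F<->G.  Every published centrality and cascade value of
that network is pinned in the test suite before any other metric test
runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MetabolicModel, MetaboliteRecord, ReactionGraph, ReactionRecord

__all__ = [
    "fig1_toy_graph",
    "SyntheticModelSpec",
    "synthetic_model",
    "random_digraph",
]

TOY_ARCS: tuple[tuple[str, str], ...] = (
    ("A", "B"), ("A", "C"), ("A", "D"),
    ("B", "D"), ("C", "D"),
    ("D", "E"), ("E", "F"),
    ("F", "G"), ("G", "F"),
)


def fig1_toy_graph() -> ReactionGraph:
    """The 7-node, 9-arc demonstration digraph (fresh copy each call)."""
    g = ReactionGraph()
    g.add_nodes_from("ABCDEFG")
    for u, v in TOY_ARCS:
        g.add_arc(u, v, {f"m_{u}{v}"})
    return g


@dataclass
class SyntheticModelSpec:
    """Shape parameters of a random metabolic model.

    Defaults mimic a small genome-scale model: a bipartite stoichiometry
    where ~80% of reactions also touch currency cofactors, a realistic
    ~30% of reversible reactions, and boundary exchange/transport
    reactions that graph construction must strip.
    """

    n_metabolites: int = 60
    n_reactions: int = 120
    reversible_fraction: float = 0.3
    n_currency: int = 5
    transport_fraction: float = 0.08
    exchange_fraction: float = 0.1
    currency_attach_prob: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for name in ("reversible_fraction", "transport_fraction",
                     "exchange_fraction", "currency_attach_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_metabolites <= 0 or self.n_reactions <= 0:
            raise ValueError("counts must be positive")
        n_boundary = int(round(self.transport_fraction * self.n_reactions)) + int(
            round(self.exchange_fraction * self.n_reactions)
        )
        if n_boundary > self.n_reactions:
            raise ValueError("more boundary reactions than reactions")


# currency names deliberately match graph_builder's default list
_CURRENCY_POOL = ("atp", "adp", "nad", "nadh", "h2o", "h", "pi", "co2", "coa", "nh4")


def synthetic_model(spec: SyntheticModelSpec) -> MetabolicModel:
    """Random metabolic model with internal, transport and exchange reactions.

    Deterministic given ``spec.seed``.  Internal reactions draw 1-3
    substrates and 1-3 products from the cytosolic metabolite pool and
    attach a currency pair with probability ``currency_attach_prob``;
    designated transport reactions move one species between compartments
    and exchange reactions have an empty product side (EX_ prefix).
    """
    rng = np.random.default_rng(spec.seed)
    model = MetabolicModel(name=f"synthetic_seed{spec.seed}")

    n_currency = min(spec.n_currency, len(_CURRENCY_POOL))
    currency = [f"{b}_c" for b in _CURRENCY_POOL[:n_currency]]
    core = [f"met{i}_c" for i in range(spec.n_metabolites)]
    external = [f"met{i}_e" for i in range(spec.n_metabolites)]
    for mid in (*core, *currency):
        model.add_metabolite(MetaboliteRecord.from_id(mid))

    n_exchange = int(round(spec.exchange_fraction * spec.n_reactions))
    n_transport = int(round(spec.transport_fraction * spec.n_reactions))
    n_internal = spec.n_reactions - n_exchange - n_transport

    added_external: set[str] = set()

    def ensure_external(i):
        mid = external[i]
        if mid not in added_external:
            model.add_metabolite(MetaboliteRecord.from_id(mid))
            added_external.add(mid)
        return mid

    for r in range(n_internal):
        ns = int(rng.integers(1, 4))
        np_ = int(rng.integers(1, 4))
        picks = rng.choice(spec.n_metabolites, size=ns + np_, replace=False)
        subs = [(core[i], 1.0) for i in picks[:ns]]
        prods = [(core[i], 1.0) for i in picks[ns:]]
        if currency and rng.random() < spec.currency_attach_prob:
            pair = rng.choice(n_currency, size=min(2, n_currency), replace=False)
            subs.append((currency[pair[0]], 1.0))
            if len(pair) > 1:
                prods.append((currency[pair[1]], 1.0))
        model.add_reaction(
            ReactionRecord(
                id=f"R{r:04d}",
                substrates=tuple(subs),
                products=tuple(prods),
                reversible=bool(rng.random() < spec.reversible_fraction),
            )
        )
    for t in range(n_transport):
        i = int(rng.integers(0, spec.n_metabolites))
        model.add_reaction(
            ReactionRecord(
                id=f"T{t:04d}",
                substrates=((ensure_external(i), 1.0),),
                products=((core[i], 1.0),),
                reversible=bool(rng.random() < spec.reversible_fraction),
            )
        )
    for x in range(n_exchange):
        i = int(rng.integers(0, spec.n_metabolites))
        model.add_reaction(
            ReactionRecord(
                id=f"EX_{x:04d}",
                substrates=((ensure_external(i), 1.0),),
                products=(),
                reversible=True,
            )
        )
    return model


def random_digraph(n: int, arc_prob: float, seed: int = 0) -> ReactionGraph:
    """Erdos-Renyi directed graph without self-arcs, seeded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= arc_prob <= 1:
        raise ValueError("arc_prob must be in [0,1]")
    rng = np.random.default_rng(seed)
    g = ReactionGraph()
    names = [f"n{i}" for i in range(n)]
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < arc_prob:
                g.add_arc(names[i], names[j], {"m"})
    return g
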