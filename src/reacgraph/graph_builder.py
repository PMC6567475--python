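"""Conversion of a metabolic model into its directed reaction graph.

An arc u -> v exists when a metabolite producible by reaction u is
consumable by reaction v.  Reversible reactions stay single nodes with
direction-union semantics: everything they touch is both producible and
consumable, so two consecutive reversible reactions form a 2-cycle.

Before construction, currency metabolites (ubiquitous cofactors such as
ATP, NAD and water) are removed from every reaction, and transport /
exchange reactions at the cell boundary are dropped — both would
otherwise create biologically meaningless short paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import MetabolicModel, ReactionGraph, ReactionRecord

__all__ = [
    "DEFAULT_CURRENCY_METABOLITES",
    "DEFAULT_BOUNDARY_PREFIXES",
    "FilterConfig",
    "classify_reaction",
    "build_reaction_graph",
    "degree",
]

# Compartment-stripped ids of ubiquitous cofactor-like species.  The
# exact list used for any published node/arc count is a modelling choice;
# this default is explicit and fully overridable via FilterConfig.
DEFAULT_CURRENCY_METABOLITES: frozenset[str] = frozenset(
    {
        "atp", "adp", "amp",
        "nad", "nadh", "nadp", "nadph",
        "h2o", "h", "pi", "ppi",
        "co2", "o2", "nh4", "coa",
        "na1", "q8", "q8h2", "fad", "fadh2",
        "gtp", "gdp", "udp", "ump", "so4",
    }
)

DEFAULT_BOUNDARY_PREFIXES: tuple[str, ...] = ("EX_", "DM_", "SK_")


@dataclass
class FilterConfig:
    """Filtering policy applied before graph construction."""

    currency_metabolites: frozenset[str] = DEFAULT_CURRENCY_METABOLITES
    boundary_prefixes: tuple[str, ...] = DEFAULT_BOUNDARY_PREFIXES
    drop_exchange: bool = True
    drop_transport: bool = True

    def __post_init__(self):
        self.currency_metabolites = frozenset(self.currency_metabolites)
        if not self.currency_metabolites:
            warnings.warn("currency metabolite list is empty; no cofactor filtering")

    @classmethod
    def from_dict(cls, data: dict) -> "FilterConfig":
        kwargs = {}
        if "currency_metabolites" in data:
            kwargs["currency_metabolites"] = frozenset(data["currency_metabolites"])
        if "boundary_prefixes" in data:
            kwargs["boundary_prefixes"] = tuple(data["boundary_prefixes"])
        for key in ("drop_exchange", "drop_transport"):
            if key in data:
                kwargs[key] = bool(data[key])
        return cls(**kwargs)


def classify_reaction(
    reaction: ReactionRecord,
    model: MetabolicModel,
    boundary_prefixes: tuple[str, ...] = DEFAULT_BOUNDARY_PREFIXES,
) -> str:
    """Classify a reaction as ``exchange``, ``transport`` or ``internal``.

    Exchange: one side empty, or a boundary id prefix (EX_/DM_/SK_ by
    default).  Transport: the multiset of compartment-stripped species is
    identical on both sides while at least one species changes
    compartment — i.e. the reaction only shuttles matter across a
    membrane.
    """
    if not reaction.substrates or not reaction.products:
        return "exchange"
    if any(reaction.id.startswith(p) for p in boundary_prefixes):
        return "exchange"

    def side_bases(side):
        bases = sorted(model.metabolites[m].species_base for m, _ in side)
        comps = {model.metabolites[m].species_base: model.metabolites[m].compartment
                 for m, _ in side}
        return bases, comps

    sub_bases, sub_comps = side_bases(reaction.substrates)
    prod_bases, prod_comps = side_bases(reaction.products)
    if sub_bases == prod_bases:
        moved = any(sub_comps[b] != prod_comps[b] for b in sub_comps)
        if moved:
            return "transport"
    return "internal"


def _effective_sides(reaction: ReactionRecord, currency: frozenset[str], model):
    subs = frozenset(
        m for m in reaction.substrate_ids
        if model.metabolites[m].species_base not in currency
    )
    prods = frozenset(
        m for m in reaction.product_ids
        if model.metabolites[m].species_base not in currency
    )
    return subs, prods


def build_reaction_graph(
    model: MetabolicModel, config: FilterConfig | None = None
) -> ReactionGraph:
    """Build the simple directed reaction graph of a metabolic model.

    Reactions whose metabolites are all currency are dropped; reactions
    isolated after filtering are kept as nodes (they matter for node
    counts and carry cascade number 0).
    """
    config = config or FilterConfig()
    graph = ReactionGraph()

    producible: dict[str, frozenset[str]] = {}
    consumable: dict[str, frozenset[str]] = {}
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        kind = classify_reaction(rxn, model, config.boundary_prefixes)
        if kind == "exchange" and config.drop_exchange:
            continue
        if kind == "transport" and config.drop_transport:
            continue
        subs, prods = _effective_sides(rxn, config.currency_metabolites, model)
        if not subs and not prods:
            continue  # nothing but currency left
        if rxn.reversible:
            producible[rid] = prods | subs
            consumable[rid] = subs | prods
        else:
            producible[rid] = prods
            consumable[rid] = subs
        graph.add_node(rid)

    # index consumers by metabolite to avoid the quadratic scan
    consumers: dict[str, list[str]] = {}
    for rid, mets in consumable.items():
        for m in mets:
            consumers.setdefault(m, []).append(rid)

    for u in graph.nodes:
        targets: dict[str, set[str]] = {}
        for m in producible[u]:
            for v in consumers.get(m, ()):
                if v != u:
                    targets.setdefault(v, set()).add(m)
        for v, mets in targets.items():
            graph.add_arc(u, v, mets)
    return graph


def degree(graph: ReactionGraph, node: str) -> tuple[int, int, int]:
    """(in, out, total) neighbor counts of ``node``.

    The graph is simple, so in/out-degree equal in/out-neighbor counts;
    a mutual pair contributes 1 to each.
    """
    if node not in graph:
        raise KeyError(node)
    d_in = graph.in_degree(node)
    d_out = graph.out_degree(node)
    return d_in, d_out, d_in + d_out
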