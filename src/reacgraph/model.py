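"""Core data structures for reaction-centric metabolic graphs.

A metabolic model is a collection of metabolites (species living in
compartments) and reactions (signed stoichiometry plus a reversibility
flag).  The derived *reaction graph* is a simple directed graph whose
nodes are reactions and whose arcs point from a producing reaction to a
consuming reaction, annotated with the mediating metabolite(s).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "MetaboliteRecord",
    "ReactionRecord",
    "MetabolicModel",
    "ReactionGraph",
    "split_compartment",
]

# BiGG-style ids carry the compartment either as a "_c" suffix or in
# "[c]" brackets; both conventions occur across model releases.
_BRACKET_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[A-Za-z0-9]+)\]$")
_SUFFIX_RE = re.compile(r"^(?P<base>.+)_(?P<comp>[A-Za-z0-9]{1,2})$")


def split_compartment(metabolite_id: str) -> tuple[str, str]:
    """Split a metabolite id into (species_base, compartment).

    Supports ``glc__D_e`` -> (``glc__D``, ``e``) and ``glc_D[e]`` ->
    (``glc_D``, ``e``).  Ids with no recognizable compartment tag are
    returned whole with an empty compartment string.
    """
    m = _BRACKET_RE.match(metabolite_id)
    if m:
        return m.group("base"), m.group("comp")
    m = _SUFFIX_RE.match(metabolite_id)
    if m:
        return m.group("base"), m.group("comp")
    return metabolite_id, ""


@dataclass(frozen=True)
class MetaboliteRecord:
    """A metabolite: id, compartment-stripped base species, compartment."""

    id: str
    species_base: str
    compartment: str

    @classmethod
    def from_id(cls, metabolite_id: str, compartment: str | None = None) -> "MetaboliteRecord":
        base, comp = split_compartment(metabolite_id)
        if compartment:  # explicit annotation (e.g. from SBML) wins
            comp = compartment
            if base == metabolite_id and metabolite_id.endswith(f"_{compartment}"):
                base = metabolite_id[: -(len(compartment) + 1)]
        if not base:
            raise ValueError(f"metabolite id {metabolite_id!r} has empty species base")
        return cls(id=metabolite_id, species_base=base, compartment=comp)


@dataclass(frozen=True)
class ReactionRecord:
    """A reaction: substrates/products as (metabolite id -> coefficient > 0)."""

    id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    reversible: bool

    def __post_init__(self):
        for side_name, side in (("substrate", self.substrates), ("product", self.products)):
            for met, coeff in side:
                if coeff <= 0:
                    raise ValueError(
                        f"reaction {self.id!r}: {side_name} {met!r} has non-positive "
                        f"coefficient {coeff}"
                    )

    @property
    def substrate_ids(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.substrates)

    @property
    def product_ids(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.products)


@dataclass
class MetabolicModel:
    """A named set of metabolites and reactions."""

    name: str
    metabolites: dict[str, MetaboliteRecord] = field(default_factory=dict)
    reactions: dict[str, ReactionRecord] = field(default_factory=dict)

    def add_metabolite(self, record: MetaboliteRecord) -> None:
        if record.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {record.id!r}")
        self.metabolites[record.id] = record

    def add_reaction(self, record: ReactionRecord) -> None:
        if record.id in self.reactions:
            raise ValueError(f"duplicate reaction id {record.id!r}")
        for met in record.substrate_ids | record.product_ids:
            if met not in self.metabolites:
                raise ValueError(
                    f"reaction {record.id!r} references unknown metabolite {met!r}"
                )
        self.reactions[record.id] = record

    def validate(self) -> None:
        for rxn in self.reactions.values():
            missing = (rxn.substrate_ids | rxn.product_ids) - self.metabolites.keys()
            if missing:
                raise ValueError(
                    f"reaction {rxn.id!r} references unknown metabolites {sorted(missing)}"
                )

    def __eq__(self, other):
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and {
                k: (frozenset(v.substrates), frozenset(v.products), v.reversible)
                for k, v in self.reactions.items()
            }
            == {
                k: (frozenset(v.substrates), frozenset(v.products), v.reversible)
                for k, v in other.reactions.items()
            }
        )


class ReactionGraph(nx.DiGraph):
    """Simple digraph of reactions; arcs carry a ``metabolites`` frozenset.

    Invariants enforced on arc insertion: no self-arcs; every arc carries
    a non-empty set of mediating metabolite ids.  Parallel arcs are
    impossible by the DiGraph container itself.
    """

    def add_arc(self, source: str, target: str, metabolites) -> None:
        if source == target:
            raise ValueError(f"self-arc {source!r} -> {target!r} is forbidden")
        mets = frozenset(metabolites)
        if not mets:
            raise ValueError(f"arc {source!r} -> {target!r} has no mediating metabolite")
        self.add_edge(source, target, metabolites=mets)

    def arc_metabolites(self, source: str, target: str) -> frozenset[str]:
        return self.edges[source, target]["metabolites"]

    def check_invariants(self) -> None:
        for u, v, data in self.edges(data=True):
            if u == v:
                raise ValueError(f"self-arc at {u!r}")
            if not data.get("metabolites"):
                raise ValueError(f"arc {u!r}->{v!r} lacks mediating metabolites")

    def equals(self, other: "ReactionGraph") -> bool:
        if set(self.nodes) != set(other.nodes):
            return False
        if set(self.edges) != set(other.edges):
            return False
        return all(
            self.arc_metabolites(u, v) == other.arc_metabolites(u, v) for u, v in self.edges
        )
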