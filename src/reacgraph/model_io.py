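"""Readers and writers: SBML models, TSV reaction tables, graph files.

The reaction-table dialect is a plain TSV with the columns
``reaction_id  reversible  substrates  products`` where the metabolite
lists are ``id:coeff`` pairs joined by ``;``.  Graphs round-trip through
either an edge TSV (``source  target  metabolite,metabolite``) or
GraphML with a ``metabolites`` arc attribute.
"""

from __future__ import annotations

import os
from pathlib import Path

import networkx as nx

from .model import MetabolicModel, MetaboliteRecord, ReactionGraph, ReactionRecord

__all__ = [
    "read_sbml_model",
    "read_reaction_table",
    "write_reaction_table",
    "write_reaction_graph",
    "read_reaction_graph",
]

EDGE_TSV_HEADER = "source\ttarget\tmetabolites"


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


def read_sbml_model(path: str | os.PathLike) -> MetabolicModel:
    """Read an SBML Level 2/3 model into a :class:`MetabolicModel`.

    A reaction is reversible when its SBML ``reversible`` attribute is
    true or its lower flux bound is negative — BiGG releases encode
    reversibility either way.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"unparsable SBML {path}: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"unparsable SBML {path}: no <model> element")

    model = MetabolicModel(name=sbml_model.getId() or Path(path).stem)
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        model.add_metabolite(
            MetaboliteRecord.from_id(sp.getId(), sp.getCompartment() or None)
        )

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        reversible = bool(rxn.getReversible())
        # FBC lower bound < 0 also marks reversibility
        fbc = rxn.getPlugin("fbc")
        if fbc is not None:
            lb_id = fbc.getLowerFluxBound()
            if lb_id and params.get(lb_id, 0.0) < 0:
                reversible = True
        kl = rxn.getKineticLaw()
        if kl is not None:
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId().upper() == "LOWER_BOUND" and p.getValue() < 0:
                    reversible = True

        def _side(n, getter):
            out = []
            for j in range(n):
                ref = getter(j)
                sid = ref.getSpecies()
                if sid not in model.metabolites:
                    raise FormatError(
                        f"reaction {rxn.getId()!r} references unknown species {sid!r}"
                    )
                coeff = ref.getStoichiometry()
                out.append((sid, float(coeff) if coeff == coeff else 1.0))
            return tuple(out)

        model.add_reaction(
            ReactionRecord(
                id=rxn.getId(),
                substrates=_side(rxn.getNumReactants(), rxn.getReactant),
                products=_side(rxn.getNumProducts(), rxn.getProduct),
                reversible=reversible,
            )
        )
    return model


def _parse_side(text: str, path, lineno: int) -> tuple[tuple[str, float], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        met, sep, coeff = item.rpartition(":")
        if not sep:
            met, coeff = item, "1"
        try:
            value = float(coeff)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: malformed coefficient {coeff!r} in {item!r}"
            ) from None
        out.append((met, value))
    return tuple(out)


def read_reaction_table(path: str | os.PathLike) -> MetabolicModel:
    """Read the TSV reaction-table dialect; metabolites are inferred."""
    model = MetabolicModel(name=Path(path).stem)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "reaction_id":  # optional header
                continue
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            rid, rev, subs, prods = fields
            if rev not in {"0", "1"}:
                raise FormatError(f"{path}:{lineno}: reversible must be 0/1, got {rev!r}")
            rows.append(
                (
                    lineno,
                    rid,
                    rev == "1",
                    _parse_side(subs, path, lineno),
                    _parse_side(prods, path, lineno),
                )
            )
    for lineno, rid, rev, subs, prods in rows:
        for met, _ in (*subs, *prods):
            if met not in model.metabolites:
                model.add_metabolite(MetaboliteRecord.from_id(met))
        if rid in model.reactions:
            raise FormatError(f"{path}:{lineno}: duplicate reaction id {rid!r}")
        model.add_reaction(
            ReactionRecord(id=rid, substrates=subs, products=prods, reversible=rev)
        )
    return model


def write_reaction_table(model: MetabolicModel, path: str | os.PathLike) -> None:
    def fmt(side):
        return ";".join(f"{m}:{c:g}" for m, c in sorted(side))

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id\treversible\tsubstrates\tproducts\n")
        for rid in sorted(model.reactions):
            r = model.reactions[rid]
            fh.write(
                f"{rid}\t{int(r.reversible)}\t{fmt(r.substrates)}\t{fmt(r.products)}\n"
            )


def write_reaction_graph(
    graph: ReactionGraph, path: str | os.PathLike, format: str = "edge-tsv"
) -> None:
    """Write a reaction graph as edge TSV (default) or GraphML.

    Edge TSV lines are emitted in lexicographic (source, target) order so
    output files are byte-reproducible.  Isolated nodes are preserved via
    ``#node`` comment lines.
    """
    graph.check_invariants()
    if format == "edge-tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(EDGE_TSV_HEADER + "\n")
            isolated = sorted(n for n in graph.nodes if graph.degree(n) == 0)
            for n in isolated:
                fh.write(f"#node\t{n}\n")
            for u, v in sorted(graph.edges):
                mets = ",".join(sorted(graph.arc_metabolites(u, v)))
                fh.write(f"{u}\t{v}\t{mets}\n")
    elif format == "graphml":
        g = nx.DiGraph()
        g.add_nodes_from(graph.nodes)
        for u, v in graph.edges:
            g.add_edge(u, v, metabolites=",".join(sorted(graph.arc_metabolites(u, v))))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_reaction_graph(path: str | os.PathLike, format: str = "edge-tsv") -> ReactionGraph:
    graph = ReactionGraph()
    if format == "edge-tsv":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line == EDGE_TSV_HEADER:
                    continue
                if line.startswith("#node\t"):
                    graph.add_node(line.split("\t", 1)[1])
                    continue
                if line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 columns")
                u, v, mets = fields
                if u == v:
                    raise FormatError(f"{path}:{lineno}: self-arc {u!r}")
                if graph.has_edge(u, v):
                    raise FormatError(f"{path}:{lineno}: duplicate arc {u!r}->{v!r}")
                graph.add_arc(u, v, mets.split(","))
    elif format == "graphml":
        g = nx.read_graphml(path)
        for n in g.nodes:
            graph.add_node(n)
        for u, v, data in g.edges(data=True):
            if u == v:
                raise FormatError(f"{path}: self-arc {u!r}")
            graph.add_arc(u, v, data["metabolites"].split(","))
    else:
        raise ValueError(f"unknown graph format {format!r}")
    graph.check_invariants()
    return graph
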