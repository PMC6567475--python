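import pytest

from reacgraph import fixtures


@pytest.fixture
def toy_graph():
    return fixtures.fig1_toy_graph()


@pytest.fixture
def toy_model():
    """The three-reaction aspartate-branch model used in the docs:
    ASAD: 4pasp <-> aspsa; HSDy: aspsa <-> hom__L; HSK: hom__L -> phom."""
    from reacgraph.model import MetabolicModel, MetaboliteRecord, ReactionRecord

    m = MetabolicModel(name="asp_branch")
    for mid in ("4pasp_c", "aspsa_c", "hom__L_c", "phom_c"):
        m.add_metabolite(MetaboliteRecord.from_id(mid))
    m.add_reaction(ReactionRecord("ASAD", (("4pasp_c", 1.0),), (("aspsa_c", 1.0),), True))
    m.add_reaction(ReactionRecord("HSDy", (("aspsa_c", 1.0),), (("hom__L_c", 1.0),), True))
    m.add_reaction(ReactionRecord("HSK", (("hom__L_c", 1.0),), (("phom_c", 1.0),), False))
    return m
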