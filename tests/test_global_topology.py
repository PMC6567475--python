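import networkx as nx
import numpy as np
import pytest

from reacgraph import fixtures, global_topology as gt
from reacgraph.model import ReactionGraph

from .oracles import brute_modularity


def two_cliques(k=5, bridge=True):
    """Two bidirectional k-cliques joined by one arc: a planted partition."""
    g = ReactionGraph()
    left = [f"L{i}" for i in range(k)]
    right = [f"R{i}" for i in range(k)]
    for group in (left, right):
        for u in group:
            for v in group:
                if u != v:
                    g.add_arc(u, v, {"m"})
    if bridge:
        g.add_arc(left[0], right[0], {"m"})
    return g, left, right


class TestDegreeDistribution:
    def test_toy_total(self, toy_graph):
        dist = gt.degree_distribution(toy_graph, "total")
        probs = dict(zip(dist.support, dist.probability))
        assert probs == {2: pytest.approx(4 / 7), 3: pytest.approx(2 / 7),
                         4: pytest.approx(1 / 7)}

    def test_single_node_has_point_mass_at_zero(self):
        g = ReactionGraph()
        g.add_node("x")
        dist = gt.degree_distribution(g)
        assert dist.support == (0,) and dist.probability == (1.0,)

    def test_regular_digraph_point_mass(self):
        g = ReactionGraph()
        for u, v in (("a", "b"), ("b", "c"), ("c", "a")):
            g.add_arc(u, v, {"m"})
        dist = gt.degree_distribution(g, "in")
        assert dist.support == (1,) and dist.probability == (1.0,)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            gt.degree_distribution(ReactionGraph())


class TestPowerLawFit:
    @pytest.mark.parametrize("gamma", [-1.3, -1.5, -2.0])
    def test_recovers_exact_exponent(self, gamma):
        support = tuple(range(1, 101))
        raw = np.array([k ** gamma for k in support])
        probs = tuple(raw / raw.sum() * 0.999)  # sums to < 1
        dist = gt.DegreeDistribution("total", support, probs)
        got, r2 = gt.fit_power_law(dist)
        assert got == pytest.approx(gamma, abs=0.02)
        assert r2 > 0.999

    def test_uniform_distribution_flat_slope(self):
        dist = gt.DegreeDistribution("total", tuple(range(1, 21)), (0.05,) * 20)
        slope, _ = gt.fit_power_law(dist)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_k_zero_excluded_from_fit(self):
        support = (0,) + tuple(range(1, 51))
        raw = np.array([k ** -1.5 for k in range(1, 51)])
        probs = (0.2,) + tuple(raw / raw.sum() * 0.8)
        slope, _ = gt.fit_power_law(gt.DegreeDistribution("total", support, probs))
        assert slope == pytest.approx(-1.5, abs=0.02)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            gt.fit_power_law(gt.DegreeDistribution("total", (1, 2), (0.5, 0.5)))

    def test_mle_sign_and_monotonicity(self):
        """The MLE diagnostic is negative and orders steeper distributions
        below shallower ones (its k_min=1 magnitude is biased by design)."""
        def mle_for(gamma):
            support = tuple(range(1, 201))
            raw = np.array([k ** gamma for k in support])
            probs = tuple(raw / raw.sum())
            got, _ = gt.fit_power_law(
                gt.DegreeDistribution("total", support, probs), method="mle"
            )
            return got

        shallow, steep = mle_for(-1.5), mle_for(-3.0)
        assert shallow < 0 and steep < 0
        assert steep < shallow


class TestModularity:
    def test_two_disjoint_two_cycles(self):
        g = ReactionGraph()
        for u, v in (("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")):
            g.add_arc(u, v, {"m"})
        part = {"a": 0, "b": 0, "c": 1, "d": 1}
        assert gt.modularity(g, part) == pytest.approx(0.5)

    def test_single_community_nonpositive(self, toy_graph):
        part = {n: 0 for n in toy_graph.nodes}
        assert gt.modularity(toy_graph, part) <= 1e-12

    def test_random_partition_near_zero(self):
        rng = np.random.default_rng(0)
        g = fixtures.random_digraph(40, 0.1, seed=1)
        qs = []
        for _ in range(20):
            part = {n: int(rng.integers(0, 4)) for n in g.nodes}
            qs.append(gt.modularity(g, part))
        assert abs(np.mean(qs)) < 0.05

    def test_missing_node_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            gt.modularity(toy_graph, {"A": 0})

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_arc_counting_oracle(self, seed):
        g = fixtures.random_digraph(9, 0.25, seed=seed)
        rng = np.random.default_rng(seed)
        part = {n: int(rng.integers(0, 3)) for n in g.nodes}
        assert gt.modularity(g, part) == pytest.approx(
            brute_modularity(list(g.nodes), list(g.edges), part)
        )

    def test_matches_networkx(self, toy_graph):
        part = {"A": 0, "B": 0, "C": 0, "D": 0, "E": 1, "F": 1, "G": 1}
        communities = [
            {n for n in part if part[n] == c} for c in sorted(set(part.values()))
        ]
        assert gt.modularity(toy_graph, part) == pytest.approx(
            nx.algorithms.community.modularity(toy_graph, communities)
        )


class TestCommunities:
    @pytest.mark.parametrize("method", ["greedy", "leiden"])
    def test_recovers_planted_cliques(self, method):
        g, left, right = two_cliques()
        part = gt.detect_communities(g, method=method, seed=7)
        assert len({part[n] for n in left}) == 1
        assert len({part[n] for n in right}) == 1
        assert part[left[0]] != part[right[0]]

    def test_empty_arcs_gives_singletons(self):
        g = ReactionGraph()
        g.add_nodes_from("abc")
        part = gt.detect_communities(g)
        assert len(set(part.values())) == 3

    def test_beats_singleton_partition(self, toy_graph):
        part = gt.detect_communities(toy_graph)
        singletons = {n: i for i, n in enumerate(toy_graph.nodes)}
        assert gt.modularity(toy_graph, part) >= gt.modularity(toy_graph, singletons)

    def test_leiden_deterministic_under_seed(self):
        g = fixtures.random_digraph(30, 0.1, seed=2)
        p1 = gt.detect_communities(g, method="leiden", seed=11)
        p2 = gt.detect_communities(g, method="leiden", seed=11)
        assert p1 == p2


class TestRandomization:
    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sequences_preserved(self, seed):
        g = fixtures.random_digraph(25, 0.12, seed=seed)
        r = gt.randomize_degree_preserving(g, seed=seed)
        assert dict(g.in_degree()) == dict(r.in_degree())
        assert dict(g.out_degree()) == dict(r.out_degree())
        assert all(u != v for u, v in r.edges)
        assert r.number_of_edges() == g.number_of_edges()

    def test_two_cycle_unchanged_with_warning(self):
        g = ReactionGraph()
        g.add_arc("a", "b", {"m"})
        g.add_arc("b", "a", {"m"})
        with pytest.warns(UserWarning):
            r = gt.randomize_degree_preserving(g, seed=0)
        assert set(r.edges) == set(g.edges)

    def test_actually_rewires(self):
        g, *_ = two_cliques()
        r = gt.randomize_degree_preserving(g, seed=3)
        assert set(r.edges) != set(g.edges)

    def test_null_modularity_below_planted(self):
        g, *_ = two_cliques()
        observed = gt.modularity(g, gt.detect_communities(g, seed=0))
        nulls = []
        for s in range(20):
            r = gt.randomize_degree_preserving(g, seed=s)
            nulls.append(gt.modularity(r, gt.detect_communities(r, seed=s)))
        assert np.mean(nulls) < observed


class TestNullTest:
    def test_planted_structure_significant(self):
        g, *_ = two_cliques()
        summary = gt.modularity_null_test(g, replicates=100, seed=5)
        assert summary.empirical_p <= 0.01
        assert summary.observed_modularity > summary.null_mean
        assert summary.null_sd >= 0
        assert summary.replicates == 100

    def test_p_never_zero(self):
        g, *_ = two_cliques()
        summary = gt.modularity_null_test(g, replicates=50, seed=1)
        assert summary.empirical_p >= 1 / 51

    def test_erdos_renyi_not_significant(self):
        g = fixtures.random_digraph(30, 0.15, seed=4)
        summary = gt.modularity_null_test(g, replicates=60, seed=4)
        assert (
            abs(summary.observed_modularity - summary.null_mean)
            <= 3 * max(summary.null_sd, 1e-9)
        )
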