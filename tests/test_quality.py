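import random
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overcover import (
    CommunityModel,
    Cover,
    QualityParams,
    community_density,
    cover_modularity,
    delta_modularity,
    fitness,
    make_clique,
    make_ring,
    weighted_modularity,
)


def round_half_up(x: float, places: int) -> float:
    q = Decimal(10) ** -places
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def model_with(n, k_in, k_out):
    return CommunityModel(members={f"v{i}" for i in range(n)}, k_in=k_in, k_out=k_out)


class TestQualityParams:
    @pytest.mark.parametrize("beta", [0.0, -0.1, 0.51, 1.0])
    def test_beta_bounds_enforced(self, beta):
        with pytest.raises(ValueError):
            QualityParams(beta=beta)

    def test_defaults(self):
        p = QualityParams()
        assert (p.beta, p.alpha, p.q_threshold, p.stability_eps) == (0.2, 1.0, 0.750, 0.015)


class TestCommunityDensity:
    def test_isolated_clique_is_one(self):
        k5 = make_clique(5)
        assert community_density(CommunityModel.from_members(k5.nodes, k5)) == 1.0

    def test_ring_of_five(self):
        c5 = make_ring(5)
        assert community_density(CommunityModel.from_members(c5.nodes, c5)) == 0.5

    def test_from_counts(self):
        assert community_density(model_with(9, 21, 11)) == pytest.approx(42 / 72)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            community_density(model_with(1, 0, 3))


class TestFitness:
    def test_clique_and_ring_indistinguishable(self):
        """An isolated clique and an isolated ring both score 1.0."""
        k5 = make_clique(5)
        c5 = make_ring(5)
        f_clique = fitness(CommunityModel.from_members(k5.nodes, k5))
        f_ring = fitness(CommunityModel.from_members(c5.nodes, c5))
        assert f_clique == f_ring == 1.0

    def test_with_boundary(self):
        assert fitness(model_with(9, 21, 11)) == pytest.approx(42 / 53)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fitness(model_with(0, 0, 0))


class TestWeightedModularity:
    #: printed per-community summaries: (n, k_in, k_out) -> Q at beta=0.2
    TABLE = [
        (9, 21, 11, 0.751),
        (7, 16, 11, 0.748),
        (8, 24, 7, 0.870),
        (18, 35, 10, 0.746),
        (16, 33, 10, 0.750),
    ]

    @pytest.mark.parametrize("n,k_in,k_out,expected", TABLE)
    def test_reference_communities(self, n, k_in, k_out, expected):
        q = weighted_modularity(model_with(n, k_in, k_out), QualityParams(beta=0.2))
        assert round_half_up(q, 3) == expected

    def test_isolated_clique_is_one_for_any_beta(self):
        k6 = make_clique(6)
        model = CommunityModel.from_members(k6.nodes, k6)
        for beta in (0.1, 0.2, 0.5):
            assert weighted_modularity(model, QualityParams(beta=beta)) == pytest.approx(1.0)

    def test_ring_scores_nine_tenths(self):
        c5 = make_ring(5)
        model = CommunityModel.from_members(c5.nodes, c5)
        assert weighted_modularity(model, QualityParams()) == pytest.approx(0.9)

    @pytest.mark.parametrize("n", range(4, 11))
    def test_separates_clique_from_ring_where_fitness_cannot(self, n):
        params = QualityParams()
        kn = make_clique(n)
        cn = make_ring(n)
        m_clique = CommunityModel.from_members(kn.nodes, kn)
        m_ring = CommunityModel.from_members(cn.nodes, cn)
        assert fitness(m_clique) == fitness(m_ring) == 1.0
        assert weighted_modularity(m_clique, params) == pytest.approx(1.0)
        assert weighted_modularity(m_ring, params) < 1.0

    def test_monotone_in_internal_and_external_edges(self):
        params = QualityParams()
        qs = [weighted_modularity(model_with(10, k, 8), params) for k in range(5, 40)]
        assert all(a < b for a, b in zip(qs, qs[1:]))
        qs = [weighted_modularity(model_with(10, 20, k), params) for k in range(0, 30)]
        assert all(a > b for a, b in zip(qs, qs[1:]))


class TestCoverModularity:
    def test_mean_of_known_pair(self):
        params = QualityParams()
        q4 = weighted_modularity(model_with(18, 35, 10), params)
        q5 = weighted_modularity(model_with(16, 33, 10), params)
        assert round_half_up((q4 + q5) / 2, 3) == 0.748

    def test_three_community_mean(self):
        params = QualityParams()
        qs = [
            weighted_modularity(model_with(*triple), params)
            for triple in [(9, 21, 11), (7, 16, 11), (8, 24, 7)]
        ]
        assert sum(qs) / 3 == pytest.approx(0.78965, abs=5e-4)

    def test_single_clique_cover(self):
        k5 = make_clique(5)
        cover = Cover()
        cover.add_community(k5.nodes)
        assert cover_modularity(cover, k5, QualityParams()) == pytest.approx(1.0)

    def test_empty_cover_rejected(self):
        with pytest.raises(ValueError):
            cover_modularity(Cover(), nx.Graph(), QualityParams())


class TestIncrementalModel:
    def test_add_isolated_node_only_grows_k_out(self):
        net = make_clique(5)
        net.add_edges_from([("x", "y"), ("x", "z")])
        model = CommunityModel.from_members(["0", "1", "2", "3", "4"], net)
        before = (model.k_in, model.k_out)
        model.add_node("x", net)
        assert model.k_in == before[0]
        assert model.k_out == before[1] + net.degree("x")

    def test_add_then_remove_is_identity(self):
        net = make_clique(6)
        model = CommunityModel.from_members(["0", "1", "2"], net)
        snapshot = (set(model.members), model.k_in, model.k_out)
        model.add_node("5", net).remove_node("5", net)
        assert (set(model.members), model.k_in, model.k_out) == snapshot

    def test_membership_preconditions(self):
        net = make_clique(4)
        model = CommunityModel.from_members(["0", "1"], net)
        with pytest.raises(ValueError):
            model.add_node("0", net)
        with pytest.raises(ValueError):
            model.remove_node("3", net)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_recount_after_random_edits(self, seed):
        """Incremental counts equal a from-scratch recount after any edit walk."""
        rng = random.Random(seed)
        n = rng.randint(4, 12)
        net = nx.gnp_random_graph(n, 0.45, seed=rng.randint(0, 2**16))
        net = nx.relabel_nodes(net, str)
        nodes = sorted(net.nodes)
        start = set(rng.sample(nodes, 2))
        model = CommunityModel.from_members(start, net)
        for _ in range(12):
            outside = [v for v in nodes if v not in model.members]
            if model.members and (not outside or rng.random() < 0.4):
                model.remove_node(rng.choice(sorted(model.members)), net)
            elif outside:
                model.add_node(rng.choice(outside), net)
            oracle = CommunityModel.from_members(model.members, net)
            assert (model.k_in, model.k_out) == (oracle.k_in, oracle.k_out)


class TestDeltaModularity:
    def test_fully_wired_candidate_gains(self):
        net = make_clique(5)
        net.add_edges_from([("x", v) for v in ["0", "1", "2", "3", "4"]])
        model = CommunityModel.from_members(["0", "1", "2", "3", "4"], net)
        assert delta_modularity(model, "x", net, QualityParams()) > 0

    def test_detached_candidate_loses(self):
        net = make_clique(5)
        net.add_edges_from([("x", "y"), ("x", "z")])
        model = CommunityModel.from_members(["0", "1", "2", "3", "4"], net)
        assert delta_modularity(model, "x", net, QualityParams()) < 0

    def test_does_not_mutate_input(self):
        net = make_clique(5)
        model = CommunityModel.from_members(["0", "1", "2"], net)
        before = (set(model.members), model.k_in, model.k_out)
        delta_modularity(model, "4", net, QualityParams())
        assert (set(model.members), model.k_in, model.k_out) == before
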