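import networkx as nx
import numpy as np
import pytest

from guildnet.cooccurrence import CooccurrenceNetwork, Edge, build_network
from guildnet.core_data import OtuTable, clr_transform, filter_otus
from guildnet.guild_discovery import (
    GuildPartition,
    bridging_subgraph,
    detect_guilds,
    guild_abundance,
    guild_abundance_mean,
    modularity,
    stable_network,
    two_set_partition,
    zipi,
)


def make_net(edges, nodes=None, label=""):
    es = tuple(Edge(i, j, r, 0.01) for i, j, r in edges)
    if nodes is None:
        nodes = tuple(sorted({n for e in es for n in e.key}))
    return CooccurrenceNetwork(tuple(nodes), es, label=label)


class TestStableNetwork:
    def test_identity(self):
        net = make_net([("a", "b", 0.5), ("b", "c", -0.4)])
        stable = stable_network(net, net)
        assert stable.n_nodes == net.n_nodes
        assert {e.key for e in stable.edges} == {e.key for e in net.edges}

    def test_sign_disagreement_excluded(self):
        a = make_net([("a", "b", 0.5), ("b", "c", 0.4)])
        b = make_net([("a", "b", -0.5), ("b", "c", 0.6)])
        stable = stable_network(a, b)
        assert [e.key for e in stable.edges] == [("b", "c")]
        lax = stable_network(a, b, require_sign_agreement=False)
        assert {e.key for e in lax.edges} == {("a", "b"), ("b", "c")}

    def test_empty_intersection_errors(self):
        a = make_net([("a", "b", 0.5)], nodes=("a", "b", "c"))
        b = make_net([("a", "c", 0.5)], nodes=("a", "b", "c"))
        with pytest.raises(ValueError, match="no stable edges"):
            stable_network(a, b)

    def test_set_intersection_oracle(self, rng):
        ga = nx.gnp_random_graph(15, 0.3, seed=11)
        gb = nx.gnp_random_graph(15, 0.3, seed=22)
        nodes = tuple(str(n) for n in range(15))
        a = make_net([(str(u), str(v), 0.5) for u, v in ga.edges()], nodes)
        b = make_net([(str(u), str(v), 0.5) for u, v in gb.edges()], nodes)
        expected = {
            tuple(sorted((str(u), str(v)))) for u, v in set(ga.edges()) & set(gb.edges())
        } | {
            tuple(sorted((str(u), str(v))))
            for u, v in ga.edges()
            if gb.has_edge(u, v)
        }
        stable = stable_network(a, b)
        assert {e.key for e in stable.edges} == expected

    def test_symmetry(self):
        a = make_net([("a", "b", 0.5), ("b", "c", 0.4), ("c", "d", -0.3)])
        b = make_net([("a", "b", 0.6), ("c", "d", -0.5)])
        sab = stable_network(a, b)
        sba = stable_network(b, a)
        assert {e.key for e in sab.edges} == {e.key for e in sba.edges}
        for e1, e2 in zip(
            sorted(sab.edges, key=lambda e: e.key),
            sorted(sba.edges, key=lambda e: e.key),
        ):
            assert (e1.rho_a, e1.rho_b) == (e2.rho_b, e2.rho_a)

    def test_param_mismatch_rejected(self):
        from guildnet.cooccurrence import NetworkParams

        a = make_net([("a", "b", 0.5)])
        b = CooccurrenceNetwork(
            ("a", "b"), (Edge("a", "b", 0.5, 0.01),), NetworkParams(rho_min=0.4)
        )
        with pytest.raises(ValueError, match="different parameters"):
            stable_network(a, b)


class TestDetectGuilds:
    def test_two_disconnected_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(5))
        nx.set_edge_attributes(g, 1.0, "weight")
        part = detect_guilds(g, seed=0, min_size=2)
        assert part.n_guilds == 2
        first = {n for n, gid in part.assignment.items() if gid == part.assignment[0]}
        assert first in ({0, 1, 2, 3}, {4, 5, 6, 7, 8})

    def test_planted_blocks_recovered(self, planted_cohort):
        from sklearn.metrics import adjusted_rand_score

        table, metadata, truth = planted_cohort
        table = filter_otus(table)
        clr = clr_transform(table)
        cond = {m.sample_id: m.condition for m in metadata}
        case = [i for i, s in enumerate(table.sample_ids) if cond[s] == "case"]
        ctrl = [i for i, s in enumerate(table.sample_ids) if cond[s] == "control"]
        net_a = build_network(clr[case], table.otu_ids, label="case")
        net_b = build_network(clr[ctrl], table.otu_ids, label="control")
        stable = stable_network(net_a, net_b)
        part = detect_guilds(stable, seed=0)
        nodes = [n for n in part.assignment if truth.membership[n] != "noise"]
        ari = adjusted_rand_score(
            [truth.membership[n] for n in nodes],
            [part.assignment[n] for n in nodes],
        )
        assert ari >= 0.8

    def test_single_edge_min_size_one(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        part = detect_guilds(g, min_size=1, seed=0)
        assert part.n_guilds in (1, 2)
        assert set(part.assignment) == {"a", "b"}

    def test_small_guilds_merged(self):
        # Two 5-cliques joined by one bridge to a pendant pair.
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 10)
        g.add_edge(10, 11)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = detect_guilds(g, min_size=3, seed=0)
        sizes = [len(part.members(k)) for k in range(part.n_guilds)]
        assert all(s >= 3 for s in sizes)

    def test_guild_ids_contiguous(self, planted_cohort):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        nx.set_edge_attributes(g, 1.0, "weight")
        part = detect_guilds(g, min_size=2, seed=0)
        assert sorted(set(part.assignment.values())) == list(range(part.n_guilds))

    def test_deterministic_under_seed(self):
        g = nx.gnp_random_graph(40, 0.15, seed=5)
        nx.set_edge_attributes(g, 1.0, "weight")
        p1 = detect_guilds(g, seed=3)
        p2 = detect_guilds(g, seed=3)
        assert p1.assignment == p2.assignment

    def test_no_edges_errors(self):
        with pytest.raises(ValueError):
            detect_guilds(nx.empty_graph(5))


class TestModularity:
    def test_two_cliques_q_half(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        partition = {n: (0 if n < 3 else 1) for n in g.nodes()}
        assert modularity(g, partition) == pytest.approx(0.5)

    def test_single_community_zero(self):
        g = nx.gnp_random_graph(10, 0.4, seed=2)
        partition = {n: 0 for n in g.nodes()}
        assert modularity(g, partition) == pytest.approx(0.0, abs=1e-12)

    def test_matches_networkx_oracle(self):
        g = nx.gnp_random_graph(20, 0.25, seed=4)
        rng = np.random.default_rng(0)
        partition = {n: int(rng.integers(0, 3)) for n in g.nodes()}
        communities = [
            {n for n in g.nodes() if partition[n] == k} for k in range(3)
        ]
        communities = [c for c in communities if c]
        expected = nx.community.modularity(g, communities)
        assert modularity(g, partition) == pytest.approx(expected, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            g = nx.gnp_random_graph(15, 0.3, seed=seed)
            if g.number_of_edges() == 0:
                continue
            partition = {n: int(rng.integers(0, 4)) for n in g.nodes()}
            q = modularity(g, partition)
            assert -0.5 <= q <= 1.0

    def test_uncovered_nodes_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="cover"):
            modularity(g, {0: 0, 1: 0})


class TestZiPi:
    def test_all_internal_links_pi_zero(self):
        g = nx.complete_graph(4)
        partition = {n: 0 for n in g.nodes()}
        scores = zipi(g, partition)
        assert all(v == 0.0 for v in scores.pi.values())

    def test_even_split_pi_half(self):
        g = nx.Graph([("x", "a"), ("x", "b")])
        partition = {"x": 0, "a": 0, "b": 1}
        scores = zipi(g, partition)
        assert scores.pi["x"] == pytest.approx(0.5)

    def test_hand_computed_table(self):
        # Module 0: {a, b, c} triangle; module 1: {d, e} edge; bridge c-d.
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("c", "d")])
        partition = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1}
        scores = zipi(g, partition)
        # within-degrees module 0: a=2, b=2, c=2 -> sd 0 -> zi 0
        assert scores.zi["a"] == 0.0 and scores.zi["c"] == 0.0
        # c has 3 links, 2 internal, 1 to module 1: pi = 1 - (4/9 + 1/9)
        assert scores.pi["c"] == pytest.approx(1 - (4 / 9 + 1 / 9))
        # d has 2 links, 1 internal, 1 external: pi = 0.5
        assert scores.pi["d"] == pytest.approx(0.5)
        assert scores.pi["e"] == 0.0

    def test_isolated_node_convention(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("iso")
        partition = {"a": 0, "b": 0, "iso": 1}
        scores = zipi(g, partition)
        assert scores.zi["iso"] == 0.0
        assert scores.pi["iso"] == 0.0

    def test_pi_below_one_and_cohesive_bound(self):
        # Every node keeps >= 60% of links internal -> all pi < 0.62.
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        g.add_edge(1, 7)
        partition = {n: (0 if n < 6 else 1) for n in g.nodes()}
        scores = zipi(g, partition)
        assert all(v < 1.0 for v in scores.pi.values())
        assert all(v < 0.62 for v in scores.pi.values())


class TestGuildAbundance:
    def _partition(self, mapping):
        n = len(set(mapping.values()))
        return GuildPartition(dict(mapping), n, 0.0)

    def test_all_otus_gives_one(self, small_table):
        part = self._partition({o: 0 for o in small_table.otu_ids})
        ab = guild_abundance(small_table, part, 0)
        assert all(v == pytest.approx(1.0) for v in ab.values())

    def test_single_otu_guild(self, small_table):
        part = self._partition({"o1": 0, "o2": 1, "o3": 1, "o4": 1})
        ab = guild_abundance(small_table, part, 0)
        assert ab["s1"] == pytest.approx(5 / 20)
        assert ab["s2"] == pytest.approx(1 / 11)

    def test_additivity(self, random_table):
        ids = list(random_table.otu_ids)
        part = self._partition(
            {o: (0 if k < 10 else 1 if k < 20 else 2) for k, o in enumerate(ids)}
        )
        total = np.zeros(random_table.n_samples)
        for g in range(3):
            ab = guild_abundance(random_table, part, g)
            total += np.array([ab[s] for s in random_table.sample_ids])
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_missing_member_warns(self, small_table):
        part = self._partition({"o1": 0, "ghost": 0})
        with pytest.warns(UserWarning, match="ghost"):
            ab = guild_abundance(small_table, part, 0)
        assert ab["s1"] == pytest.approx(5 / 20)

    def test_no_members_present_errors(self, small_table):
        part = self._partition({"ghost1": 0, "ghost2": 0})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no guild member"):
                guild_abundance(small_table, part, 0)

    def test_mean_variant(self, small_table):
        part = self._partition({"o1": 0, "o2": 0, "o3": 1, "o4": 1})
        s = guild_abundance(small_table, part, 0)
        m = guild_abundance_mean(small_table, part, 0)
        for sid in small_table.sample_ids:
            assert m[sid] == pytest.approx(s[sid] / 2)

    def test_planted_shift_direction(self):
        from guildnet.synthetic_data import (
            GuildSpec,
            SyntheticCohortSpec,
            generate_cohort,
        )

        guilds = GuildSpec(
            sizes=(6, 5),
            rho_intra_case=0.5,
            rho_intra_control=0.5,
            abundance_log_shift=(0.8, 0.0),
        )
        cohort = SyntheticCohortSpec(n_case=120, n_control=120, n_noise_otus=20, seed=5)
        table, metadata, truth = generate_cohort(guilds, cohort)
        part = self._partition(
            {
                o: (0 if g == "guild0" else 1 if g == "guild1" else 2)
                for o, g in truth.membership.items()
            }
        )
        ab = guild_abundance(table, part, 0)
        cond = {m.sample_id: m.condition for m in metadata}
        case_mean = np.mean([v for s, v in ab.items() if cond[s] == "case"])
        ctrl_mean = np.mean([v for s, v in ab.items() if cond[s] == "control"])
        assert case_mean > ctrl_mean


class TestBridgingSubgraph:
    def test_no_cross_edges_is_empty_not_error(self):
        net = make_net([("a", "b", 0.5), ("c", "d", 0.5)])
        sub = bridging_subgraph(net, {"a", "b"}, {"c", "d"})
        assert sub.n_edges == 0

    def test_complete_bipartite(self):
        net = make_net(
            [("a1", "b1", 0.5), ("a1", "b2", 0.5), ("a2", "b1", 0.5), ("a2", "b2", 0.5)]
        )
        sub = bridging_subgraph(net, {"a1", "a2"}, {"b1", "b2"})
        assert sub.n_edges == 4
        from guildnet.cooccurrence import topology

        assert topology(sub).mean_degree == pytest.approx(2.0)

    def test_overlapping_sets_error(self):
        net = make_net([("a", "b", 0.5)])
        with pytest.raises(ValueError, match="overlap"):
            bridging_subgraph(net, {"a"}, {"a", "b"})

    def test_filter_oracle(self):
        g = nx.gnp_random_graph(16, 0.3, seed=9)
        nodes = tuple(str(n) for n in g.nodes())
        net = make_net([(str(u), str(v), 0.5) for u, v in g.edges()], nodes)
        set_a = {str(n) for n in range(8)}
        set_b = {str(n) for n in range(8, 16)}
        sub = bridging_subgraph(net, set_a, set_b)
        expected = {
            tuple(sorted((str(u), str(v))))
            for u, v in g.edges()
            if (str(u) in set_a) != (str(v) in set_a)
        }
        assert {e.key for e in sub.edges} == expected

    def test_two_set_partition_modularity(self):
        net = make_net(
            [("a1", "b1", 0.5), ("a1", "b2", 0.5), ("a2", "b1", 0.5), ("a2", "b2", 0.5)]
        )
        sub = bridging_subgraph(net, {"a1", "a2"}, {"b1", "b2"})
        partition = two_set_partition(sub, {"a1", "a2"}, {"b1", "b2"})
        # purely bipartite cut: no within-community edges
        q = modularity(sub, partition)
        assert q == pytest.approx(-0.5)
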