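"""Tests for residue interaction networks, centrality, communities, bridgeness."""

import itertools

import networkx as nx
import numpy as np
import pytest

import alloscan as al
from conftest import make_toy_network


def brute_force_betweenness(network):
    """Oracle: enumerate every simple path, keep the co-optimal shortest ones.

    Independent of the Floyd–Warshall implementation; feasible for <= 8 nodes.
    """
    g = network.graph
    nodes = sorted(g.nodes)
    between = {v: 0.0 for v in nodes}
    for j, k in itertools.combinations(nodes, 2):
        paths = []
        try:
            all_paths = nx.all_simple_paths(g, j, k)
        except nx.NodeNotFound:
            continue
        for p in all_paths:
            w = sum(g[a][b]["weight"] for a, b in zip(p, p[1:]))
            paths.append((w, p))
        if not paths:
            continue
        best = min(w for w, _ in paths)
        shortest = [p for w, p in paths if w <= best + 1e-9]
        for v in nodes:
            if v in (j, k):
                continue
            through = sum(1 for p in shortest if v in p)
            if through:
                between[v] += through / len(shortest)
    return np.array([between[v] for v in nodes])


class TestBuildNetwork:
    def test_edge_weights_follow_minus_log_R(self):
        ids = np.arange(1, 5)
        frac = np.zeros((4, 4))
        frac[0, 2] = frac[2, 0] = 1.0       # persistent contact
        frac[1, 3] = frac[3, 1] = 1.0
        np.fill_diagonal(frac, 1.0)
        pm = al.PersistenceMatrix(ids, frac, cutoff=5.0, min_fraction=0.75)
        r = np.eye(4)
        r[0, 2] = r[2, 0] = np.exp(-1.0)    # weight exactly 1
        r[1, 3] = r[3, 1] = 1.0             # weight floors near 0
        gc = al.CorrelationMatrix(ids, r, "gc")
        net = al.build_network(pm, gc)
        assert net.graph[1][3]["weight"] == pytest.approx(1.0, abs=1e-12)
        assert net.graph[2][4]["weight"] == pytest.approx(0.0, abs=1e-9)
        assert net.graph.number_of_edges() == 2

    def test_zero_R_edges_dropped(self):
        ids = np.arange(1, 4)
        frac = np.ones((3, 3))
        pm = al.PersistenceMatrix(ids, frac, cutoff=5.0, min_fraction=0.75)
        r = np.eye(3)
        r[0, 2] = r[2, 0] = 0.0
        gc = al.CorrelationMatrix(ids, r, "gc")
        net = al.build_network(pm, gc)
        assert net.graph.number_of_edges() == 0  # only 1-3 was non-covalent


class TestShortestPaths:
    def test_path_graph_distances_and_counts(self):
        net = make_toy_network([(1, 2, 1.0), (2, 3, 1.0)])
        sp = al.shortest_paths(net)
        assert sp.dist[0, 2] == pytest.approx(2.0)
        assert sp.counts[0, 2] == 1

    def test_square_cycle_has_two_shortest_paths_across(self):
        net = make_toy_network([(1, 2, 1.0), (2, 3, 1.0), (3, 4, 1.0), (4, 1, 1.0)])
        sp = al.shortest_paths(net)
        assert sp.dist[0, 2] == pytest.approx(2.0)
        assert sp.counts[0, 2] == 2

    def test_disconnected_pairs_have_infinite_distance(self):
        net = make_toy_network([(1, 2, 1.0)], n_nodes=3)
        sp = al.shortest_paths(net)
        assert np.isinf(sp.dist[0, 2]) and sp.counts[0, 2] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_distances_match_dijkstra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(1 << 30)))
        edges = [(u + 1, v + 1, rng.uniform(0.1, 2.0)) for u, v in g.edges]
        net = make_toy_network(edges, n_nodes=8)
        sp = al.shortest_paths(net)
        oracle = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
        for i, u in enumerate(sp.nodes):
            for j, v in enumerate(sp.nodes):
                expected = oracle.get(u, {}).get(v, np.inf)
                assert sp.dist[i, j] == pytest.approx(expected, abs=1e-9)


class TestBetweenness:
    def test_five_node_path_center_hand_count(self):
        net = make_toy_network([(i, i + 1, 1.0) for i in range(1, 5)])
        prof = al.betweenness_profile(al.shortest_paths(net))
        # center (node 3) lies on the unique shortest paths of {1,4},{1,5},{2,4},{2,5}
        assert prof.betweenness[2] == pytest.approx(4.0)
        assert prof.betweenness.tolist() == pytest.approx([0.0, 3.0, 4.0, 3.0, 0.0])

    @pytest.mark.parametrize("n_leaves", [4, 7])
    def test_star_center_closed_form(self, n_leaves):
        net = make_toy_network([(1, i, 1.0) for i in range(2, n_leaves + 2)])
        prof = al.betweenness_profile(al.shortest_paths(net))
        assert prof.betweenness[0] == pytest.approx(n_leaves * (n_leaves - 1) / 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.55, seed=int(rng.integers(1 << 30)))
        edges = [(u + 1, v + 1, float(rng.uniform(0.1, 2.0))) for u, v in g.edges]
        net = make_toy_network(edges, n_nodes=n)
        ours = al.betweenness_profile(al.shortest_paths(net)).betweenness
        assert ours == pytest.approx(brute_force_betweenness(net), abs=1e-8)

    def test_z_scores_standardize(self):
        net = make_toy_network([(i, i + 1, 1.0) for i in range(1, 8)])
        prof = al.betweenness_profile(al.shortest_paths(net))
        assert prof.z_scores.mean() == pytest.approx(0.0, abs=1e-12)
        assert prof.z_scores.std() == pytest.approx(1.0, abs=1e-12)

    def test_equal_centrality_yields_no_hotspots(self):
        net = make_toy_network(
            [(1, 2, 1.0), (2, 3, 1.0), (3, 4, 1.0), (4, 1, 1.0)]
        )
        prof = al.betweenness_profile(al.shortest_paths(net))
        assert prof.hotspots == [] and np.all(prof.z_scores == 0.0)


class TestCommunities:
    def test_two_cliques_joined_by_one_edge(self):
        edges = [(u, v, 1.0) for u, v in itertools.combinations(range(1, 6), 2)]
        edges += [(u, v, 1.0) for u, v in itertools.combinations(range(6, 11), 2)]
        edges.append((5, 6, 1.0))
        net = make_toy_network(edges)
        part = al.detect_communities(net)
        assert sorted(map(sorted, part.communities)) == [
            [1, 2, 3, 4, 5],
            [6, 7, 8, 9, 10],
        ]
        assert part.modularity > 0.3

    def test_complete_graph_stays_one_community(self):
        edges = [(u, v, 1.0) for u, v in itertools.combinations(range(1, 7), 2)]
        part = al.detect_communities(make_toy_network(edges))
        assert len(part.communities) == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_planted_three_community_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        spec = al.PlantedNetworkSpec(
            community_sizes=[14, 14, 14],
            bridge_nodes=[4, 18],
            intra_corr=0.5,
            inter_corr=0.0,
            bridge_corr=0.3,
        )
        ens = al.generate_correlated_ensemble(spec, n_models=300, seed=2)
        pm = al.contact_persistence(ens, cutoff=5.0, min_fraction=0.75)
        gc = al.gc_matrix(ens, estimator="gaussian", superpose=False)
        part = al.detect_communities(al.build_network(pm, gc), max_communities=8)
        planted = spec.membership()
        nodes = sorted(part.membership)
        # the bridge nodes sit between communities by construction; their
        # planted membership is ambiguous, so score the unambiguous nodes
        keep = [i for i in range(len(nodes)) if i not in spec.bridge_nodes]
        detected = [part.membership[nodes[i]] for i in keep]
        assert adjusted_rand_score(planted[keep], detected) >= 0.9


class TestBridgeness:
    def test_internal_node_scores_zero_and_single_bridge_scores_one(self):
        edges = [(1, 2, 1.0), (1, 3, 1.0), (2, 3, 1.0), (3, 4, 1.0),
                 (4, 5, 1.0), (4, 6, 1.0), (5, 6, 1.0)]
        net = make_toy_network(edges)
        part = al.CommunityPartition(
            membership={1: 0, 2: 0, 3: 0, 4: 1, 5: 1, 6: 1}, modularity=0.0
        )
        prof = al.bridgeness_profile(net, part)
        values = dict(zip(prof.nodes, prof.bridgeness))
        assert values[1] == 0.0 and values[2] == 0.0   # internal-only nodes
        assert values[3] == 1.0 and values[4] == 1.0   # the 3-4 link, l = 1/1

    def test_hand_computed_seven_node_example(self):
        edges = [(1, 2, 1.0), (2, 3, 1.0), (1, 3, 1.0),   # community A = {1,2,3}
                 (4, 5, 1.0),                              # community B = {4,5}
                 (6, 7, 1.0),                              # community C = {6,7}
                 (3, 4, 1.0),                              # A-B (1 link)
                 (3, 6, 1.0), (1, 7, 1.0),                 # A-C (2 links)
                 (5, 6, 1.0)]                              # B-C (1 link)
        net = make_toy_network(edges)
        part = al.CommunityPartition(
            membership={1: 0, 2: 0, 3: 0, 4: 1, 5: 1, 6: 2, 7: 2}, modularity=0.0
        )
        prof = al.bridgeness_profile(net, part)
        values = dict(zip(prof.nodes, prof.bridgeness))
        assert values == pytest.approx(
            {1: 0.5, 2: 0.0, 3: 1.5, 4: 1.0, 5: 1.0, 6: 1.5, 7: 0.5}
        )

    def test_partition_must_cover_nodes(self):
        net = make_toy_network([(1, 2, 1.0)])
        part = al.CommunityPartition(membership={1: 0}, modularity=0.0)
        with pytest.raises(ValueError, match="cover"):
            al.bridgeness_profile(net, part)


class TestPlantedBridgeRecovery:
    def test_bridge_node_is_top_betweenness_hotspot(self, planted_bridge_network):
        prof = al.betweenness_profile(al.shortest_paths(planted_bridge_network))
        top = prof.nodes[int(np.argmax(prof.betweenness))]
        assert top == 6              # bridge node index 5 -> residue id 6
        assert prof.z_scores[prof.nodes.index(6)] >= 2.0
        assert 6 in prof.hotspots

    def test_bridge_attains_maximal_bridgeness(self, planted_bridge_network):
        part = al.detect_communities(planted_bridge_network, max_communities=6)
        prof = al.bridgeness_profile(planted_bridge_network, part)
        values = dict(zip(prof.nodes, prof.bridgeness))
        assert values[6] == max(values.values())
        # nodes with intra-community edges only score exactly zero
        g = planted_bridge_network.graph
        for node in prof.nodes:
            if all(part.membership[nb] == part.membership[node] for nb in g.neighbors(node)):
                assert values[node] == 0.0

    def test_edge_removal_never_shrinks_distances(self, planted_bridge_network):
        g = planted_bridge_network.graph.copy()
        sp_before = al.shortest_paths(al.ResidueInteractionNetwork(g, planted_bridge_network.gc))
        eb = nx.edge_betweenness_centrality(g, weight="weight")
        g2 = g.copy()
        g2.remove_edge(*max(eb, key=eb.get))
        sp_after = al.shortest_paths(al.ResidueInteractionNetwork(g2, planted_bridge_network.gc))
        assert np.all(sp_after.dist >= sp_before.dist - 1e-12)


class TestMutationMapping:
    @pytest.fixture()
    def profile_and_coords(self):
        prof = al.CentralityProfile(
            nodes=[1, 2, 3, 4, 5],
            betweenness=np.array([0.0, 0.0, 10.0, 0.0, 0.0]),
            z_scores=np.array([-0.5, -0.5, 2.0, -0.5, -0.5]),
            hotspots=[3],
        )
        coords = {
            1: np.array([0.0, 0.0, 0.0]),
            2: np.array([4.0, 0.0, 0.0]),
            3: np.array([8.0, 0.0, 0.0]),
            4: np.array([12.0, 0.0, 0.0]),
            5: np.array([14.0, 0.0, 0.0]),
        }
        return prof, coords

    def test_direct_proximal_distal_classification(self, profile_and_coords):
        prof, coords = profile_and_coords
        mapping = al.map_mutations([3, 2, 4, 5], prof, coords, proximity=5.0)
        t = mapping.table.set_index("site")
        assert t.loc[3, "status"] == "direct_hotspot" and t.loc[3, "distance"] == 0.0
        assert t.loc[2, "status"] == "proximal" and t.loc[2, "distance"] == pytest.approx(4.0)
        assert t.loc[4, "status"] == "proximal"
        assert t.loc[5, "status"] == "distal" and t.loc[5, "distance"] == pytest.approx(6.0)

    def test_absent_site_rejected(self, profile_and_coords):
        prof, coords = profile_and_coords
        with pytest.raises(ValueError, match="99"):
            al.map_mutations([99], prof, coords)
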