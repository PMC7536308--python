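from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from phenotraj.core import ObservationTable
from phenotraj.mapper import build_mapper_graph, pairwise_distance
from phenotraj.trajectories import (
    Trajectory,
    _exhaustive_communities,
    _greedy_communities,
    assign_subjects,
    edge_time_weights,
    extract_trajectories,
    index_weights,
    jaccard_similarity,
    map_observations_to_nodes,
    minimum_spanning_tree,
    modularity_score,
    optimal_communities,
    select_root,
)

# the worked assignment example: one subject trajectory against three mined ones
TI = [41, 42, 43, 39, 40, 33, 34, 26, 27, 19]
TD1 = [41, 37, 30, 22, 15, 8, 1]
TD2 = [41, 42, 43, 39, 32, 24, 17, 10, 3]
TD3 = [41, 42, 43, 39, 40, 33, 34, 26, 19, 12, 5]


class TestCommunities:
    def test_two_triangles_split_into_two_communities(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        part = optimal_communities(g)
        assert not part.approximate
        comms = part.communities()
        assert sorted(map(sorted, comms)) == [[0, 1, 2], [3, 4, 5]]

    def test_single_node_graph(self):
        g = nx.Graph()
        g.add_node(0)
        part = optimal_communities(g)
        assert part.membership == {0: 0}
        assert part.modularity == 0.0

    def test_edgeless_graph_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        part = optimal_communities(g)
        assert len(set(part.membership.values())) == 4

    def test_modularity_matches_networkx(self):
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        part = optimal_communities(g, exhaustive_max_nodes=4)
        groups = part.communities()
        assert part.modularity == pytest.approx(
            nx.community.modularity(g, groups), abs=1e-12)

    def test_exhaustive_matches_igraph_exact_solver(self):
        igraph = pytest.importorskip("igraph")
        for seed in (0, 1, 2):
            g = nx.gnp_random_graph(8, 0.4, seed=seed)
            _, q = _exhaustive_communities(g)
            gi = igraph.Graph(n=8, edges=list(g.edges()))
            q_ig = gi.modularity(gi.community_optimal_modularity())
            assert q == pytest.approx(q_ig, abs=1e-9)

    def test_greedy_reaches_exhaustive_optimum_on_random_graphs(self):
        for seed in range(10):
            g = nx.gnp_random_graph(10, 0.3, seed=seed)
            if g.number_of_edges() == 0:
                continue
            _, q_ex = _exhaustive_communities(g)
            q_gr = modularity_score(g, _greedy_communities(g))
            assert q_gr == pytest.approx(q_ex, abs=1e-9)

    def test_partition_beats_singletons(self):
        g = nx.gnp_random_graph(14, 0.3, seed=9)
        part = optimal_communities(g)
        assert part.approximate
        singletons = {n: i for i, n in enumerate(g.nodes())}
        assert part.modularity >= modularity_score(g, singletons) - 1e-12


class TestEdgeWeights:
    def _graph(self):
        return build_mapper_graph([
            ((0, 0), [frozenset({0, 1})]),
            ((0, 1), [frozenset({1, 2})]),
            ((1, 0), [frozenset({2, 3})]),
        ])

    def test_time_weights_average_shared_rows(self):
        g = self._graph()
        w = edge_time_weights(g, np.array([0.0, 200.0, 100.0, 0.0]))
        assert w[(0, 1)] == 200.0  # single shared row 1
        assert w[(1, 2)] == 100.0

    def test_time_weight_two_shared_rows(self):
        g = build_mapper_graph([((0, 0), [frozenset({0, 1})]), ((0, 1), [frozenset({0, 1})])],)
        w = edge_time_weights(g, np.array([100.0, 300.0]))
        assert w[(0, 1)] == 200.0

    def test_index_weights_absolute_difference(self):
        g = self._graph()
        w = index_weights(g)
        assert w == {(0, 1): 1.0, (1, 2): 1.0}


class TestMinimumSpanningTree:
    def test_path_graph_is_its_own_mst(self):
        g = nx.path_graph(5)
        w = {(u, v): 1.0 for u, v in g.edges()}
        tree = minimum_spanning_tree(g, w)
        assert sorted(tree.edges()) == sorted(g.edges())

    def test_four_cycle_drops_heaviest_edge(self):
        g = nx.cycle_graph(4)
        w = {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0, (0, 3): 5.0}
        tree = minimum_spanning_tree(g, w)
        assert (0, 3) not in tree.edges() and (3, 0) not in tree.edges()
        assert tree.number_of_edges() == 3

    def test_total_weight_matches_exhaustive_minimum(self):
        # enumerate all spanning trees of random <=8-node graphs
        rng = np.random.default_rng(0)
        for seed in range(8):
            g = nx.gnp_random_graph(rng.integers(4, 9), 0.6, seed=seed)
            if not nx.is_connected(g):
                g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
            if g.number_of_nodes() < 2:
                continue
            edges = [(min(u, v), max(u, v)) for u, v in g.edges()]
            w = {e: float(rng.integers(1, 10)) for e in edges}
            n = g.number_of_nodes()
            best = np.inf
            for subset in combinations(edges, n - 1):
                t = nx.Graph(subset)
                if t.number_of_nodes() == n and nx.is_connected(t):
                    best = min(best, sum(w[e] for e in subset))
            tree = minimum_spanning_tree(g, w)
            got = sum(w[(min(u, v), max(u, v))] for u, v in tree.edges())
            assert got == pytest.approx(best)

    def test_edge_count_per_component(self):
        g = nx.Graph([(0, 1), (1, 2), (3, 4)])
        w = {(0, 1): 1.0, (1, 2): 1.0, (3, 4): 1.0}
        tree = minimum_spanning_tree(g, w)
        comps = list(nx.connected_components(tree))
        assert len(comps) == 2
        for comp in comps:
            assert tree.subgraph(comp).number_of_edges() == len(comp) - 1

    def test_deterministic_under_ties(self):
        g = nx.complete_graph(5)
        w = {(min(u, v), max(u, v)): 1.0 for u, v in g.edges()}
        t1 = minimum_spanning_tree(g, w)
        t2 = minimum_spanning_tree(g, w)
        assert sorted(t1.edges()) == sorted(t2.edges())


class TestExtractTrajectories:
    def test_star_with_early_center(self):
        tree = nx.star_graph(3)  # center 0
        mean_time = {0: 0.0, 1: 5.0, 2: 5.0, 3: 5.0}
        trajs = extract_trajectories(tree, mean_time)
        assert [t.node_ids for t in trajs] == [[0, 1], [0, 2], [0, 3]]

    def test_path_with_earliest_endpoint(self):
        tree = nx.path_graph(3)
        trajs = extract_trajectories(tree, {0: 0.0, 1: 1.0, 2: 2.0})
        assert [t.node_ids for t in trajs] == [[0, 1, 2]]

    def test_single_node_tree(self):
        tree = nx.Graph()
        tree.add_node(7)
        trajs = extract_trajectories(tree, {7: 0.0})
        assert [t.node_ids for t in trajs] == [[7]]

    def test_trajectory_count_equals_leaf_count(self):
        for seed in range(20):
            tree = nx.random_labeled_tree(10, seed=seed)
            mean_time = {n: float(n) for n in tree.nodes()}
            root = 0
            leaves = [n for n in tree.nodes() if tree.degree(n) == 1 and n != root]
            trajs = extract_trajectories(tree, mean_time)
            assert len(trajs) == len(leaves)

    def test_terminal_community_filled_from_partition(self):
        tree = nx.path_graph(3)
        part = optimal_communities(nx.path_graph(3))
        trajs = extract_trajectories(tree, {0: 0.0, 1: 1.0, 2: 2.0}, part)
        assert trajs[0].terminal_community == part.membership[2]

    def test_root_selection_prefers_tree_leaves(self):
        g = build_mapper_graph([
            ((0, 0), [frozenset({0, 4})]),
            ((0, 1), [frozenset({0, 1, 2, 4})]),
            ((0, 2), [frozenset({2, 3})]),
        ])
        time = np.array([0.0, 0.0, 5.0, 9.0, 0.0])
        # interior node 1 holds the most first-observation rows...
        assert select_root(g, time) == 1
        # ...but with the tree given, the best leaf (node 0) is the root
        tree = minimum_spanning_tree(g, index_weights(g))
        assert select_root(g, time, tree) == 0


class TestJaccard:
    def test_worked_example_values(self):
        assert jaccard_similarity(TI, TD1) == pytest.approx(0.0625)
        assert jaccard_similarity(TI, TD2) == pytest.approx(0.2667, abs=5e-5)
        assert jaccard_similarity(TI, TD3) == pytest.approx(0.75)

    def test_identity_and_disjoint(self):
        assert jaccard_similarity([1, 2, 3], [3, 2, 1]) == 1.0
        assert jaccard_similarity([1, 2], [3, 4]) == 0.0

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = rng.integers(0, 10, rng.integers(1, 8)).tolist()
            b = rng.integers(0, 10, rng.integers(1, 8)).tolist()
            s = jaccard_similarity(a, b)
            assert 0.0 <= s <= 1.0
            assert s == jaccard_similarity(b, a)
            assert (s == 1.0) == (set(a) == set(b))


class TestSubjectAssignment:
    def test_worked_example_assigns_to_third_trajectory(self):
        mined = [Trajectory(TD1), Trajectory(TD2), Trajectory(TD3)]
        individuals = {"i": Trajectory(TI, kind="individual", subject="i")}
        out = assign_subjects(individuals, mined)
        idx, sim = out["i"]
        assert idx == 2
        assert sim == pytest.approx(0.75)

    def test_single_mined_trajectory_is_forced(self):
        out = assign_subjects({"s": Trajectory([9], kind="individual")}, [Trajectory([1, 2])])
        assert out["s"][0] == 0

    def test_tie_breaks_toward_lowest_index(self):
        mined = [Trajectory([1, 2]), Trajectory([2, 3])]
        out = assign_subjects({"s": Trajectory([2], kind="individual")}, mined)
        assert out["s"][0] == 0


class TestMapObservationsToNodes:
    def _table(self, features, subjects=None, times=None):
        n = len(features)
        return ObservationTable(
            subject_ids=np.array(subjects or ["s"] * n, dtype=object),
            time_days=np.array(times if times is not None else np.arange(n, dtype=float)),
            labels=np.zeros(n, dtype=int),
            features=np.asarray(features, dtype=float),
            feature_names=["x"],
        )

    def test_row_in_single_node_is_forced(self):
        g = build_mapper_graph([((0, 0), [frozenset({0, 1})])])
        table = self._table([[0.0], [1.0]])
        D = pairwise_distance(table.features, "euclidean")
        out = map_observations_to_nodes(g, table, D)
        assert out["s"].node_ids == [0]

    def test_all_encounters_in_one_node_compress_to_length_one(self):
        g = build_mapper_graph([((0, 0), [frozenset({0, 1, 2})])])
        table = self._table([[0.0], [0.5], [1.0]])
        D = pairwise_distance(table.features, "euclidean")
        out = map_observations_to_nodes(g, table, D)
        assert out["s"].node_ids == [0]

    def test_overlap_resolved_to_nearest_members(self):
        # row 1 sits exactly on node 0's other member; node 1's members are far
        g = build_mapper_graph([
            ((0, 0), [frozenset({0, 1})]),
            ((0, 1), [frozenset({1, 2, 3})]),
        ])
        table = self._table([[0.0], [0.0], [10.0], [11.0]])
        D = pairwise_distance(table.features, "euclidean")
        out = map_observations_to_nodes(g, table, D)
        assert out["s"].node_ids[0] == 0

    def test_subject_order_follows_time(self):
        g = build_mapper_graph([
            ((0, 0), [frozenset({0})]),
            ((0, 1), [frozenset({1})]),
        ])
        table = self._table([[0.0], [5.0]], subjects=["s", "s"], times=[100.0, 0.0])
        D = pairwise_distance(table.features, "euclidean")
        out = map_observations_to_nodes(g, table, D)
        assert out["s"].node_ids == [1, 0]

    def test_every_covered_subject_receives_one_assignment(self, small_cohort):
        from phenotraj.core import normalize_features
        from phenotraj.mapper import MapperConfig, build_mapper

        norm, _ = normalize_features(small_cohort)
        D = pairwise_distance(norm.features, "cosine")
        g, _ = build_mapper(norm.features, MapperConfig(num_intervals=4, gain=0.5), D=D)
        individuals = map_observations_to_nodes(g, small_cohort, D)
        mined = [Trajectory(list(g.node_ids))]
        out = assign_subjects(individuals, mined)
        assert set(out) == set(individuals)
        assert len(individuals) == len(set(small_cohort.subject_ids))
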