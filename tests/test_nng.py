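"""Navigation game: navigation sets, exact set cover, equilibrium
navigability and edge classification."""

import itertools

import numpy as np
import pytest

from navopt.distances import euclidean_distance_matrix, validate_distance_matrix
from navopt.nng import (
    NNGNetwork,
    build_nng,
    classify_edges,
    greedy_route,
    navigability,
    navigation_set,
    optimal_navigation_vector,
)
from navopt.synthetic import gen_coords


def brute_minimum_cover_size(sets_by_candidate, universe):
    """Independent oracle: exhaustive enumeration over all subsets."""
    candidates = sorted(sets_by_candidate)
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            if set().union(*(sets_by_candidate[c] for c in combo)) >= universe:
                return size
    raise AssertionError("no cover")


class TestDistanceValidation:
    def test_rejects_duplicate_points(self):
        coords = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1], [2, 2, 2]])
        with pytest.raises(ValueError, match="positive"):
            validate_distance_matrix(euclidean_distance_matrix(coords))

    def test_rejects_asymmetry_and_nonzero_diagonal(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            validate_distance_matrix(D)
        with pytest.raises(ValueError):
            validate_distance_matrix(np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestNavigationSet:
    def test_collinear_points(self, line_coords):
        # u=0, v=1, w=2 on a line: d(v,w)=1 < d(u,w)=2 so both v and w
        # are reachable through v
        D = euclidean_distance_matrix(line_coords)
        assert navigation_set(0, 1, D) == {1, 2}

    def test_far_candidate_covers_only_itself(self):
        # v is farther from every third node than u is: S_v^u = {v}
        coords = np.array([[0, 0, 0], [100, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        D = euclidean_distance_matrix(coords)
        assert navigation_set(0, 1, D) == {1}

    def test_union_over_candidates_is_everything(self, small_layout):
        _, D = small_layout
        n = D.shape[0]
        for u in range(n):
            union = set()
            for v in range(n):
                if v != u:
                    union |= navigation_set(u, v, D)
            assert union == set(range(n)) - {u}

    def test_candidate_always_member_and_source_never(self, small_layout):
        _, D = small_layout
        for u, v in [(0, 5), (3, 1), (7, 11)]:
            s = navigation_set(u, v, D)
            assert v in s and u not in s

    def test_identical_nodes_rejected(self, small_layout):
        _, D = small_layout
        with pytest.raises(ValueError):
            navigation_set(2, 2, D)


class TestMinimumCover:
    def test_hand_instance_size_two(self):
        # universe {1,2,3} with S1={1,2}, S2={2,3}, S3={3}: brute force
        # over all 7 nonempty subsets gives minimum cover size 2
        sets = {1: {1, 2}, 2: {2, 3}, 3: {3}}
        assert brute_minimum_cover_size(sets, {1, 2, 3}) == 2

    def test_two_nodes_single_choice(self):
        D = euclidean_distance_matrix(np.array([[0, 0, 0], [1, 0, 0.0]]))
        assert optimal_navigation_vector(0, D) == frozenset({1})

    @pytest.mark.parametrize("seed", range(12))
    def test_solver_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        coords = rng.uniform(0, 50, size=(n, 3))
        D = euclidean_distance_matrix(coords)
        for u in range(n):
            sets = {v: navigation_set(u, v, D) for v in range(n) if v != u}
            oracle = brute_minimum_cover_size(sets, set(range(n)) - {u})
            chosen = optimal_navigation_vector(u, D, method="milp")
            assert len(chosen) == oracle
            # solver result is itself a cover
            union = set().union(*(sets[v] for v in chosen))
            assert union >= set(range(n)) - {u}

    @pytest.mark.parametrize("seed", range(6))
    def test_milp_and_brute_agree_on_tie_break(self, seed):
        coords = gen_coords(9, seed=seed)
        D = euclidean_distance_matrix(coords)
        for u in range(9):
            assert (optimal_navigation_vector(u, D, method="milp")
                    == optimal_navigation_vector(u, D, method="brute"))

    def test_every_chosen_set_necessary(self, small_layout):
        _, D = small_layout
        n = D.shape[0]
        for u in range(n):
            chosen = optimal_navigation_vector(u, D)
            universe = set(range(n)) - {u}
            for dropped in chosen:
                rest = chosen - {dropped}
                union = set().union(
                    *(navigation_set(u, v, D) for v in rest)
                ) if rest else set()
                assert not union >= universe


class TestBuildNNG:
    def test_tetrahedron_connected_and_navigable(self, tetrahedron):
        D = euclidean_distance_matrix(tetrahedron)
        nng = build_nng(D)
        assert navigability(nng.adjacency, D) == 1.0
        # all pairwise distances equal, so S_v^u = {v} (strict
        # inequality fails for every other target): each node must
        # connect to all three others and the equilibrium is complete
        assert all(len(c) == 3 for c in nng.chosen)
        assert nng.n_edges == 6

    def test_two_nodes_single_edge(self):
        D = euclidean_distance_matrix(np.array([[0, 0, 0], [3, 0, 0.0]]))
        nng = build_nng(D)
        assert nng.n_edges == 1

    def test_deterministic_across_reruns(self, small_layout):
        _, D = small_layout
        a = build_nng(D)
        b = build_nng(D)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert a.chosen == b.chosen

    def test_block_mode_equals_per_block_runs(self):
        coords = gen_coords(16, seed=5)
        D = euclidean_distance_matrix(coords)
        blocks = np.array([0] * 8 + [1] * 8)
        whole = build_nng(D, blocks=blocks)
        assert np.array_equal(
            whole.adjacency[:8, :8],
            build_nng(D[:8, :8]).adjacency,
        )
        assert np.array_equal(
            whole.adjacency[8:, 8:],
            build_nng(D[8:, 8:]).adjacency,
        )
        assert not whole.adjacency[:8, 8:].any()


class TestGreedyRoute:
    def test_direct_edge_is_direct_hop(self, small_layout):
        _, D = small_layout
        adj = np.zeros_like(D, dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        assert greedy_route(adj, D, 0, 1) == [0, 1]

    def test_empty_adjacency_fails(self, small_layout):
        _, D = small_layout
        adj = np.zeros_like(D, dtype=int)
        assert greedy_route(adj, D, 0, 1) is None

    def test_source_equals_target_rejected(self, small_layout):
        _, D = small_layout
        with pytest.raises(ValueError):
            greedy_route(np.ones_like(D, dtype=int), D, 2, 2)

    def test_complete_graph_fully_navigable(self, small_layout):
        _, D = small_layout
        n = D.shape[0]
        adj = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
        assert navigability(adj, D) == 1.0

    def test_isolated_node_limits_navigability(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [5, 5, 5.0]])
        D = euclidean_distance_matrix(coords)
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        assert navigability(adj, D) <= 2 / 6

    @pytest.mark.parametrize("seed", range(5))
    def test_nng_always_fully_navigable(self, seed):
        coords = gen_coords(15, seed=seed)
        D = euclidean_distance_matrix(coords)
        nng = build_nng(D)
        assert navigability(nng.adjacency, D) == 1.0


class TestClassifyEdges:
    def _nng(self, D):
        return build_nng(D)

    def test_identical_edge_sets(self, small_layout):
        _, D = small_layout
        nng = self._nng(D)
        S = nng.adjacency * 0.5
        cls = classify_edges(S, nng)
        assert cls.optimality == 1.0
        assert cls.n_false_positives == 0
        assert len(cls.optimal) + cls.n_false_positives == cls.n_nng_edges

    def test_empty_structural_network(self, small_layout):
        _, D = small_layout
        nng = self._nng(D)
        cls = classify_edges(np.zeros_like(D), nng)
        assert cls.optimality == 0.0
        assert cls.n_false_positives == cls.n_nng_edges

    def test_extra_edges_become_nonoptimal(self, small_layout):
        _, D = small_layout
        nng = self._nng(D)
        S = nng.adjacency.astype(float)
        added = 0
        n = D.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if S[i, j] == 0 and added < 5:
                    S[i, j] = S[j, i] = 0.7
                    added += 1
        cls = classify_edges(S, nng)
        assert cls.optimality == 1.0
        assert len(cls.nonoptimal) == 5

    def test_dimension_mismatch_rejected(self, small_layout):
        _, D = small_layout
        nng = self._nng(D)
        with pytest.raises(ValueError):
            classify_edges(np.zeros((3, 3)), nng)

    def test_count_identity_holds(self, small_layout):
        _, D = small_layout
        nng = self._nng(D)
        rng = np.random.default_rng(0)
        S = np.triu(rng.random((D.shape[0],) * 2) < 0.3, 1).astype(float)
        S = S + S.T
        cls = classify_edges(S, nng)
        assert len(cls.optimal) + cls.n_false_positives == cls.n_nng_edges
        assert 0.0 <= cls.optimality <= 1.0
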