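"""Spanning trees, stability filtering and complexity indices."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cohortnet.autocm import SimilarityMatrix
from cohortnet.datamodel import expand_indicators
from cohortnet.graphs import (
    GraphError,
    group_complexity_contrast,
    h_index,
    hub_nodes,
    maximally_regular_graph,
    meta_mst,
    minimum_spanning_tree,
    pruning_cycles,
    topological_entropy,
)
from cohortnet.synthdata import generate_contrast_cohort
from conftest import random_binary_matrix


def brute_force_mst_weight(D: np.ndarray) -> float:
    """Exhaustive minimum over all n^(n-2) spanning trees via Prüfer decode."""
    import heapq

    n = D.shape[0]
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        heap = [i for i in range(n) if degree[i] == 1]
        heapq.heapify(heap)
        total = 0.0
        for v in seq:
            leaf = heapq.heappop(heap)
            total += D[leaf, v]
            degree[v] -= 1
            if degree[v] == 1:
                heapq.heappush(heap, v)
        # the heap now holds exactly the two ends of the last edge
        total += D[heapq.heappop(heap), heapq.heappop(heap)]
        best = min(best, total)
    return best


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    D = rng.random((n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


class TestMST:
    def test_three_node_enumeration(self):
        D = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.2], [0.5, 0.2, 0.0]])
        T = minimum_spanning_tree(D, ["1", "2", "3"])
        assert set(map(frozenset, T.edges())) == {frozenset({"1", "2"}), frozenset({"2", "3"})}
        assert sum(d["distance"] for _, _, d in T.edges(data=True)) == pytest.approx(0.3)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_total_weight_matches_exhaustive_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            D = random_distance_matrix(rng, n)
            T = minimum_spanning_tree(D)
            total = sum(d["distance"] for _, _, d in T.edges(data=True))
            assert total == pytest.approx(brute_force_mst_weight(D), abs=1e-9)

    def test_matches_networkx_kruskal_weight(self):
        rng = np.random.default_rng(99)
        D = random_distance_matrix(rng, 12)
        T = minimum_spanning_tree(D)
        G = nx.Graph()
        for i in range(12):
            for j in range(i + 1, 12):
                G.add_edge(i, j, weight=D[i, j])
        ref = nx.minimum_spanning_tree(G, algorithm="kruskal")
        assert sum(d["distance"] for _, _, d in T.edges(data=True)) == pytest.approx(
            ref.size(weight="weight")
        )

    def test_tree_facts_on_every_build(self):
        rng = np.random.default_rng(7)
        for n in (3, 6, 10):
            T = minimum_spanning_tree(random_distance_matrix(rng, n))
            assert T.number_of_edges() == n - 1
            assert nx.is_connected(T)
            assert nx.is_forest(T)

    def test_all_equal_distances_gives_lexicographically_first_tree(self):
        labels = ["a", "b", "c", "d"]
        D = np.ones((4, 4)) - np.eye(4)
        T = minimum_spanning_tree(D, labels)
        # Kruskal scans (a,b),(a,c),(a,d),... -> the star rooted at 'a'
        assert set(map(tuple, map(sorted, T.edges()))) == {
            ("a", "b"), ("a", "c"), ("a", "d")
        }

    def test_non_finite_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.inf
        with pytest.raises(GraphError):
            minimum_spanning_tree(D)


class TestComplexityIndices:
    def test_path_has_zero_hubness(self):
        assert h_index(nx.path_graph(5)) == 0.0

    @pytest.mark.parametrize("n", range(4, 21))
    def test_star_closed_form(self, n):
        assert h_index(nx.star_graph(n - 1)) == pytest.approx((n - 3) / (n - 2))

    def test_degree_sequence_example(self):
        # tree with degree sequence (3,3,1,1,1,1): two adjacent hubs with
        # two leaves each -> H = (1+1)/4
        T = nx.Graph([(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)])
        assert h_index(T) == pytest.approx(0.5)

    def test_h_stays_within_unit_interval_on_dense_graphs(self):
        for G in (nx.complete_graph(6), nx.cycle_graph(7), nx.wheel_graph(8)):
            assert 0.0 <= h_index(G) <= 1.0

    def test_h_non_decreasing_for_edges_between_busy_nodes(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            G = nx.random_labeled_tree(10, seed=int(rng.integers(1e6)))
            candidates = [
                (u, v)
                for u in G for v in G
                if u < v and not G.has_edge(u, v)
                and G.degree(u) >= 2 and G.degree(v) >= 2
            ]
            if not candidates:
                continue
            u, v = candidates[0]
            before = h_index(G)
            G.add_edge(u, v)
            assert h_index(G) >= before - 1e-12

    @pytest.mark.parametrize(
        "graph,expected",
        [
            (nx.path_graph(4), 2),   # two waves of leaf stripping
            (nx.star_graph(5), 2),   # leaves, then the isolated centre
            (nx.cycle_graph(3), 1),  # one min-degree wave removes the cycle
        ],
    )
    def test_pruning_cycle_counts(self, graph, expected):
        assert pruning_cycles(graph) == expected

    def test_topological_entropy_star4(self):
        # A=3, P=2, degrees (3,1,1,1): H_S = 1.79248, E_G = 1.5 * H_S
        assert topological_entropy(nx.star_graph(3)) == pytest.approx(2.689, abs=1e-3)

    def test_topological_entropy_single_edge(self):
        assert topological_entropy(nx.path_graph(2)) == pytest.approx(1.0)

    def test_added_edge_with_same_pruning_depth_raises_arc_ratio(self):
        G = nx.cycle_graph(6)
        before_ratio = G.number_of_edges() / pruning_cycles(G)
        G.add_edge(0, 3)
        assert pruning_cycles(G) >= 1
        assert G.number_of_edges() / pruning_cycles(G) > before_ratio or \
            pruning_cycles(G) > 1


class TestHubNodes:
    def test_star_centre_ranks_first(self):
        ranked = hub_nodes(nx.star_graph(5))
        assert ranked[0] == (0, 5)

    def test_path_ties_break_by_label(self):
        G = nx.path_graph(5)  # internal nodes 1,2,3 tie at degree 2
        ranked = hub_nodes(G)
        assert [n for n, _ in ranked[:3]] == [1, 2, 3]


class TestMRG:
    def _sim(self, S, labels):
        return SimilarityMatrix(S=S, labels=labels)

    def test_no_candidates_returns_the_mst(self):
        labels = list("abcd")
        S = np.eye(4)
        S[0, 1] = S[1, 0] = 0.9
        S[1, 2] = S[2, 1] = 0.8
        S[2, 3] = S[3, 2] = 0.7
        sim = self._sim(S, labels)
        G, report = maximally_regular_graph(sim, floor=0.33)
        assert G.number_of_edges() == 3
        assert report.A == 3 and report.H == h_index(G)

    def test_cycle_closure_can_leave_hubness_unchanged(self):
        """Path a-b-c-d plus the strong a-d link: the re-added edge closes
        a cycle between two degree-1 nodes, incrementing A while H stays
        at the path's zero."""
        labels = list("abcd")
        S = np.eye(4)
        for i, j, s in ((0, 1, 0.9), (1, 2, 0.85), (2, 3, 0.8), (0, 3, 0.5)):
            S[i, j] = S[j, i] = s
        G, report = maximally_regular_graph(self._sim(S, labels), floor=0.33)
        mst_edges = 3
        assert report.A == mst_edges + 1
        assert report.H == 0.0
        assert G.has_edge("a", "d")

    def test_two_block_data_yields_a_loop_per_block(self):
        """Two duplicated column blocks: the MRG re-introduces within-block
        links, closing at least one cycle inside each block."""
        from cohortnet.autocm import saturating_C, similarity_matrix, train_autocm

        rng = np.random.default_rng(1)
        base = (rng.random((150, 2)) < 0.4).astype(float)
        blocks, labels = [], []
        for b, tag in enumerate("AB"):
            blk = np.repeat(base[:, [b]], 4, axis=1)
            flip = rng.random(blk.shape) < 0.05  # slight noise to avoid ties
            blocks.append(np.abs(blk - flip))
            labels += [f"{tag}{i}" for i in range(4)]
        X = np.hstack(blocks)
        model = train_autocm(X, labels=labels, C=saturating_C(X))
        G, _ = maximally_regular_graph(similarity_matrix(model))
        for tag in "AB":
            sub = G.subgraph([n for n in G if n.startswith(tag)])
            # a connected block subgraph with >= as many edges as nodes
            # necessarily contains a cycle
            assert sub.number_of_edges() >= sub.number_of_nodes()

    def test_mrg_contains_the_mst_and_is_at_least_as_hubby(self):
        rng = np.random.default_rng(2)
        X = random_binary_matrix(rng, 100, 8)
        from cohortnet.autocm import saturating_C, similarity_matrix, train_autocm
        from cohortnet.graphs import mst_from_similarity

        sim = similarity_matrix(train_autocm(X, C=saturating_C(X)))
        mst = mst_from_similarity(sim)
        G, report = maximally_regular_graph(sim, mst=mst)
        for e in mst.edges():
            assert G.has_edge(*e)
        assert report.H >= h_index(mst) - 1e-12


class TestMetaMST:
    def test_no_dropping_reproduces_the_mst_exactly(self):
        from cohortnet.autocm import similarity_matrix, train_autocm
        from cohortnet.graphs import mst_from_similarity

        rng = np.random.default_rng(3)
        X = random_binary_matrix(rng, 60, 7)
        mst = mst_from_similarity(similarity_matrix(train_autocm(X)))
        meta = meta_mst(X, k=10, drop_fraction=0.0, support_threshold=10, seed=0)
        assert set(map(frozenset, meta.edges())) == set(map(frozenset, mst.edges()))
        assert all(d["support"] == 10 for _, _, d in meta.edges(data=True))

    def test_support_thresholds_are_nested(self):
        rng = np.random.default_rng(4)
        X = random_binary_matrix(rng, 50, 6)
        g10 = meta_mst(X, k=10, support_threshold=10, seed=5)
        g9 = meta_mst(X, k=10, support_threshold=9, seed=5)
        assert set(map(frozenset, g10.edges())) <= set(map(frozenset, g9.edges()))

    def test_duplicated_block_edges_reach_full_support(self):
        rng = np.random.default_rng(5)
        base = random_binary_matrix(rng, 80, 3)
        X = np.hstack([base, base[:, [0]], base[:, [1]]])  # cols 3,4 duplicate 0,1
        meta = meta_mst(X, k=10, support_threshold=10, seed=6)
        assert meta.has_edge("col0", "col3")
        assert meta.has_edge("col1", "col4")


class TestGroupContrast:
    def test_identical_groups_have_zero_deltas(self):
        rng = np.random.default_rng(6)
        X = random_binary_matrix(rng, 40, 6)
        Xx = np.vstack([X, X])
        outcome = np.concatenate([np.ones(40, int), np.zeros(40, int)])
        gc = group_complexity_contrast(Xx, outcome, min_rows=10)
        assert gc.delta_H == 0.0
        assert gc.delta_E_G == 0.0

    def test_report_carries_both_groups_bookkeeping(self):
        coh = generate_contrast_cohort(n_per_group=60, seed=0)
        m = expand_indicators(coh)
        gc = group_complexity_contrast(m.feature_frame(), coh.outcome)
        for rep in (gc.case, gc.control):
            assert rep.A >= 1 and rep.P >= 1
            # histogram counts nodes; handshake: sum(deg * count) = 2A
            assert sum(d * c for d, c in rep.degree_histogram.items()) == 2 * rep.A

    def test_tiny_group_rejected(self):
        rng = np.random.default_rng(7)
        X = random_binary_matrix(rng, 30, 5)
        outcome = np.array([1] * 5 + [0] * 25)
        with pytest.raises(GraphError):
            group_complexity_contrast(X, outcome, min_rows=20)
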