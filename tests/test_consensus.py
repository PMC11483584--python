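import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tauscape as ts
from tauscape.consensus import EnumerationCapExceeded
from tauscape.io import ValidationError
from tauscape.regions import RankingSet
from helpers_oracles import brute_force_common_subsequences, brute_force_lcs


def _rankings(*orderings):
    ids = sorted(orderings[0])
    return RankingSet(region_ids=ids, orderings=[list(o) for o in orderings])


class TestMaxConsensus:
    def test_identical_orderings_conserve_everything(self):
        order = [3, 1, 4, 2, 5]
        length, witness = ts.max_consensus(_rankings(order, order, order))
        assert length == 5
        assert list(witness.region_ids) == order

    def test_reversed_pair_conserves_single_region_only(self):
        length, witness = ts.max_consensus(_rankings([1, 2, 3, 4], [4, 3, 2, 1]))
        assert length == 1
        assert len(witness) == 1

    def test_witness_is_order_conserved_in_every_sample(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            orders = [list(rng.permutation(10)) for _ in range(3)]
            ids = sorted(orders[0])
            rs = RankingSet(region_ids=ids, orderings=orders)
            length, witness = ts.max_consensus(rs)
            assert len(witness) == length
            for order in orders:
                pos = {r: i for i, r in enumerate(order)}
                assert all(
                    pos[a] < pos[b]
                    for a, b in zip(witness.region_ids, witness.region_ids[1:])
                )

    def test_agrees_with_exhaustive_enumeration_on_small_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(2, 8))
            orders = [list(map(int, rng.permutation(n))) for _ in range(3)]
            rs = RankingSet(region_ids=list(range(n)), orderings=orders)
            assert ts.max_consensus(rs)[0] == brute_force_lcs(orders)

    def test_invariant_under_region_relabelling(self):
        rng = np.random.default_rng(9)
        orders = [list(map(int, rng.permutation(9))) for _ in range(3)]
        base = ts.max_consensus(RankingSet(region_ids=list(range(9)),
                                           orderings=orders))[0]
        relabel = {i: 100 + 7 * i for i in range(9)}
        relabelled = [[relabel[r] for r in o] for o in orders]
        assert ts.max_consensus(
            RankingSet(region_ids=sorted(relabel.values()), orderings=relabelled)
        )[0] == base

    def test_invariant_under_common_permutation_of_samples(self):
        rng = np.random.default_rng(10)
        orders = [list(map(int, rng.permutation(9))) for _ in range(3)]
        base = ts.max_consensus(RankingSet(region_ids=list(range(9)),
                                           orderings=orders))[0]
        sigma = list(map(int, rng.permutation(9)))
        mapped = [[sigma[r] for r in o] for o in orders]
        assert ts.max_consensus(RankingSet(region_ids=list(range(9)),
                                           orderings=mapped))[0] == base

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(2, 7), st.integers(1, 4), st.randoms(use_true_random=False))
    def test_length_bounds_and_witness_validity(self, n, k, rnd):
        """1 <= max length <= n, and the witness is conserved everywhere."""
        orders = []
        for _ in range(k):
            o = list(range(n))
            rnd.shuffle(o)
            orders.append(o)
        rs = RankingSet(region_ids=list(range(n)), orderings=orders)
        length, witness = ts.max_consensus(rs)
        assert 1 <= length <= n
        for order in orders:
            pos = {r: i for i, r in enumerate(order)}
            assert all(pos[a] < pos[b]
                       for a, b in zip(witness.region_ids, witness.region_ids[1:]))

    def test_non_permutation_input_rejected(self):
        with pytest.raises(ValidationError, match="permutation"):
            RankingSet(region_ids=[1, 2, 3], orderings=[[1, 2, 3], [1, 1, 2]])


class TestEnumerateSequences:
    def test_identical_orderings_have_unique_full_sequence(self):
        rs = _rankings([1, 2, 3, 4], [1, 2, 3, 4])
        seqs = ts.enumerate_sequences(rs, 4)
        assert [list(s.region_ids) for s in seqs] == [[1, 2, 3, 4]]

    def test_three_sample_toy_matches_brute_force(self):
        orders = [[1, 2, 3], [1, 3, 2], [2, 1, 3]]
        rs = _rankings(*orders)
        seqs = ts.enumerate_sequences(rs, 2)
        assert [s.region_ids for s in seqs] == [(1, 3)]
        assert brute_force_common_subsequences(orders, 2) == [(1, 3)]

    def test_random_instances_match_brute_force_at_every_length(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            orders = [list(map(int, rng.permutation(n))) for _ in range(3)]
            rs = RankingSet(region_ids=list(range(n)), orderings=orders)
            top = ts.max_consensus(rs)[0]
            for L in range(1, top + 1):
                got = [s.region_ids for s in ts.enumerate_sequences(rs, L)]
                assert got == brute_force_common_subsequences(orders, L)

    def test_length_beyond_maximum_is_empty(self):
        rs = _rankings([1, 2, 3], [3, 2, 1])
        assert ts.enumerate_sequences(rs, 2) == []

    def test_cap_aborts_with_named_error(self):
        order = list(range(12))
        rs = _rankings(order, order)
        with pytest.raises(EnumerationCapExceeded):
            ts.enumerate_sequences(rs, 6, cap=10)


class TestUniquePatterns:
    def test_subsequences_of_the_maximal_chain_are_excluded(self):
        rs = _rankings([1, 2, 3], [1, 2, 3])
        patterns = ts.unique_patterns(rs)
        assert [s.region_ids for s in patterns[3]] == [(1, 2, 3)]
        assert patterns[2] == []

    def test_partially_overlapping_sequence_is_retained(self):
        # (1,2,3) maximal; (1,4) conserved but inside no longer chain
        rs = _rankings([1, 2, 3, 4], [1, 4, 2, 3])
        patterns = ts.unique_patterns(rs)
        assert [s.region_ids for s in patterns[3]] == [(1, 2, 3)]
        assert [s.region_ids for s in patterns[2]] == [(1, 4)]

    def test_descent_stops_at_min_length(self):
        rs = _rankings([1, 2, 3, 4], [1, 2, 3, 4])
        patterns = ts.unique_patterns(rs, min_length=3)
        assert sorted(patterns) == [3, 4]

    def test_exact_containment_mode_keeps_subsequences(self):
        rs = _rankings([1, 2, 3], [1, 2, 3])
        patterns = ts.unique_patterns(rs, containment="exact")
        assert len(patterns[2]) == 3  # (1,2),(1,3),(2,3) all kept


class TestPermutationNull:
    def test_single_sample_always_reaches_full_length(self):
        null = ts.permutation_null(6, 1, n_perm=50, seed=0)
        assert np.all(null.max_lengths == 6)
        assert null.p_at[6] == 1.0

    def test_tail_probabilities_non_increasing(self, null_10k):
        values = [null_10k.p_at[L] for L in range(1, 48)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_threshold_non_increasing_in_alpha(self, null_10k):
        thresholds = []
        for alpha in (0.2, 0.05, 0.01):
            null = ts.NullDistribution(
                n_regions=47, k_samples=3, n_perm=null_10k.n_perm, alpha=alpha,
                seed=None, max_lengths=null_10k.max_lengths,
            )
            thresholds.append(null.threshold_length)
        assert thresholds == sorted(thresholds)

    def test_same_seed_reproduces_distribution(self):
        a = ts.permutation_null(10, 3, n_perm=200, seed=4)
        b = ts.permutation_null(10, 3, n_perm=200, seed=4)
        np.testing.assert_array_equal(a.max_lengths, b.max_lengths)


class TestPlantedConsensusRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_planted_chain_found_at_its_length(self, seed):
        planted = tuple(range(1, 13))
        rs = ts.make_ranking_set(ts.PlantedConsensusSpec(47, 3, planted, seed=seed))
        length, _ = ts.max_consensus(rs)
        assert length >= 12
        witnesses = ts.enumerate_sequences(rs, 12)
        assert ts.ConsensusSequence(planted) in witnesses


class TestConsensusGraph:
    def test_single_sequence_weights_follow_caption_rule(self):
        seq = ts.ConsensusSequence((1, 2, 3))
        graph = ts.build_graph([seq], weight_total=250.0)
        weights = {
            (u, v): d["weight"] for u, v, d in graph.graph.edges(data=True)
        }
        assert weights == {(1, 2): pytest.approx(125.0), (2, 3): pytest.approx(125.0)}

    def test_shared_edge_outweighs_unshared_three_to_two(self):
        seqs = [ts.ConsensusSequence((1, 2, 3)), ts.ConsensusSequence((1, 2, 4))]
        graph = ts.build_graph(seqs)
        edges = {(u, v): d for u, v, d in graph.graph.edges(data=True)}
        assert edges[(1, 2)]["adjacency"] == 2
        ratio = edges[(1, 2)]["weight"] / edges[(2, 3)]["weight"]
        assert ratio == pytest.approx(3 / 2)

    def test_total_weight_is_exactly_the_normalization_constant(self, rng):
        for _ in range(20):
            n_seq = int(rng.integers(1, 8))
            seqs = []
            for _ in range(n_seq):
                length = int(rng.integers(2, 9))
                ids = rng.choice(30, size=length, replace=False)
                seqs.append(ts.ConsensusSequence(tuple(int(i) for i in ids)))
            graph = ts.build_graph(seqs, weight_total=250.0)
            assert abs(graph.total_weight - 250.0) < 1e-9

    def test_empty_sequence_list_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            ts.build_graph([])

    def test_node_ranks_attached(self):
        graph = ts.build_graph([ts.ConsensusSequence((5, 9))],
                               mean_density_ranks={5: 0, 9: 1})
        assert graph.graph.nodes[5]["rank"] == 0


class TestLayout:
    def test_layout_is_deterministic_given_seed(self):
        graph = ts.build_graph([ts.ConsensusSequence((1, 2, 3))])
        a = ts.layout_graph(graph, seed=3)
        b = ts.layout_graph(graph, seed=3)
        for node in a:
            np.testing.assert_array_equal(a[node], b[node])

    def test_two_nodes_are_separated(self):
        graph = ts.build_graph([ts.ConsensusSequence((1, 2))])
        pos = ts.layout_graph(graph, seed=0)
        assert np.linalg.norm(pos[1] - pos[2]) > 0

    def test_empty_graph_has_empty_layout(self):
        import networkx as nx

        empty = ts.ConsensusGraph(graph=nx.DiGraph(), weight_total=250.0)
        assert ts.layout_graph(empty, seed=0) == {}
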