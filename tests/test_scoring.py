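"""Weighted-vote scoring: worked example, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluidvote as fv
from conftest import oracle_scores, random_instance

# per-fluid confidence sums of the worked example, first re-derived by the
# independent loop oracle in test_worked_example_matches_oracle
PGRP1_EXPECTED = {6: 4.282, 7: 2.202, 11: 2.126, 2: 0.532}


class TestScoreQuery:
    def test_worked_example_matches_oracle(self, vocab, pgrp):
        net, ann = pgrp
        edges = net.edges()
        labels = {p: ann.labels(p) for p in ann}
        expected = oracle_scores("O75594", edges, labels, vocab.numbers)
        got = fv.score_query("O75594", net, ann, vocab)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        for fluid, value in PGRP1_EXPECTED.items():
            assert got[vocab.index_of(fluid)] == pytest.approx(value, abs=1e-9)

    def test_isolated_query_scores_zero(self, vocab, pgrp):
        net, ann = pgrp
        assert not fv.score_query("UNKNOWN", net, ann, vocab).any()

    def test_single_neighbor_single_fluid(self, vocab):
        net = fv.InteractionNetwork.from_edges([("Q", "T", 0.4)])
        ann = fv.AnnotationTable({"T": {3}})
        s = fv.score_query("Q", net, ann, vocab)
        assert s[vocab.index_of(3)] == pytest.approx(0.4)
        assert s.sum() == pytest.approx(0.4)

    def test_exclusion_removes_contributions(self, vocab, pgrp):
        net, ann = pgrp
        full = fv.score_query("O75594", net, ann, vocab)
        without = fv.score_query("O75594", net, ann, vocab, exclude={"P61626"})
        diff = full - without
        for f in (1, 2, 3, 4, 6, 7, 8, 10, 11):
            assert diff[vocab.index_of(f)] == pytest.approx(0.532)
        # self-exclusion is a no-op: the diagonal is already zero
        np.testing.assert_array_equal(
            full, fv.score_query("O75594", net, ann, vocab, exclude={"O75594"})
        )

    def test_unannotated_neighbors_contribute_nothing(self, vocab):
        net = fv.InteractionNetwork.from_edges([("Q", "T", 0.4), ("Q", "U", 0.9)])
        ann = fv.AnnotationTable({"T": {3}})  # U has no annotation
        s = fv.score_query("Q", net, ann, vocab)
        assert s.sum() == pytest.approx(0.4)


class TestScoreAll:
    @pytest.mark.parametrize("seed", range(10))
    def test_matrix_product_equals_bruteforce(self, seed):
        edges, labels, net, ann, vocab = random_instance(seed, n=30, F=6)
        sm = fv.score_all(list(ann.proteins), net, ann, vocab)
        for i, q in enumerate(sm.queries):
            expected = oracle_scores(q, edges, labels, vocab.numbers)
            assert np.max(np.abs(sm.scores[i] - expected)) < 1e-12

    def test_row_sum_conservation(self):
        # sum over fluids of s(q, .) equals sum over neighbors of w * m(t)
        edges, labels, net, ann, vocab = random_instance(7, n=25, F=5)
        sm = fv.score_all(list(ann.proteins), net, ann, vocab)
        for i, q in enumerate(sm.queries):
            expected = sum(
                net.confidence(q, t) * len(labels[t]) for t in net.neighbors(q)
            )
            assert sm.scores[i].sum() == pytest.approx(expected, abs=1e-12)

    def test_empty_query_list(self, vocab, pgrp):
        net, ann = pgrp
        sm = fv.score_all([], net, ann, vocab)
        assert sm.scores.shape == (0, 11)

    def test_duplicate_queries_rejected(self, vocab, pgrp):
        net, ann = pgrp
        with pytest.raises(ValueError, match="duplicate"):
            fv.score_all(["O75594", "O75594"], net, ann, vocab)

    def test_label_permutation_equivariance(self):
        # renaming fluids by a permutation permutes score entries identically
        edges, labels, net, ann, vocab = random_instance(11, n=20, F=5)
        rng = np.random.default_rng(0)
        perm = {old: int(new) for old, new in
                zip(vocab.numbers, rng.permutation(vocab.numbers))}
        ann2 = fv.AnnotationTable(
            {p: {perm[f] for f in labels[p]} for p in labels}
        )
        sm1 = fv.score_all(list(ann.proteins), net, ann, vocab)
        sm2 = fv.score_all(list(ann.proteins), net, ann2, vocab)
        for old in vocab.numbers:
            i_old, i_new = vocab.index_of(old), vocab.index_of(perm[old])
            np.testing.assert_allclose(sm1.scores[:, i_old], sm2.scores[:, i_new])

    def test_adding_neighbor_monotonic_in_its_fluid_only(self, vocab):
        net = fv.InteractionNetwork.from_edges([("Q", "T", 0.4)])
        ann = fv.AnnotationTable({"T": {3}, "U": {5}})
        before = fv.score_query("Q", net, ann, vocab)
        net.add_edge("Q", "U", 0.25)
        after = fv.score_query("Q", net, ann, vocab)
        assert after[vocab.index_of(5)] > before[vocab.index_of(5)]
        mask = np.arange(vocab.F) != vocab.index_of(5)
        np.testing.assert_array_equal(after[mask], before[mask])


class TestRanking:
    def test_worked_example_order(self, vocab, pgrp):
        net, ann = pgrp
        s = fv.score_query("O75594", net, ann, vocab)
        pred = fv.rank_fluids(s, vocab, query="O75594")
        assert pred.order[:3] == (6, 7, 11)
        assert pred.predictable
        assert fv.top_fluid(s, vocab) == 6

    def test_illustrative_three_fluid_ordering(self, vocab):
        # a score profile peaking at cerebrospinal fluid, then plasma, then urine
        s = np.zeros(11)
        s[vocab.index_of(3)] = 0.9
        s[vocab.index_of(6)] = 0.6
        s[vocab.index_of(11)] = 0.3
        assert fv.rank_fluids(s, vocab).order[:3] == (3, 6, 11)

    def test_all_zero_vector_is_unpredictable(self, vocab):
        s = np.zeros(11)
        assert fv.top_fluid(s, vocab) is None
        pred = fv.rank_fluids(s, vocab)
        assert not pred.predictable
        assert pred.order == vocab.numbers  # index tie policy

    def test_one_hot_vector(self, vocab):
        s = np.zeros(11)
        s[vocab.index_of(9)] = 1.0
        assert fv.top_fluid(s, vocab) == 9

    def test_uniform_ties_index_policy(self, vocab):
        pred = fv.rank_fluids(np.ones(11), vocab)
        assert pred.order == tuple(range(1, 12))
        assert fv.top_fluid(np.ones(11), vocab) == 1

    def test_random_tie_policy_is_seeded_and_valid(self, vocab):
        s = np.ones(11)
        p1 = fv.rank_fluids(s, vocab, tie_policy="random",
                            rng=np.random.default_rng(42))
        p2 = fv.rank_fluids(s, vocab, tie_policy="random",
                            rng=np.random.default_rng(42))
        p3 = fv.rank_fluids(s, vocab, tie_policy="random",
                            rng=np.random.default_rng(43))
        assert p1.order == p2.order
        assert sorted(p1.order) == list(vocab.numbers)
        assert p1.order != p3.order  # a different seed shuffles differently
        with pytest.raises(ValueError, match="rng"):
            fv.rank_fluids(s, vocab, tie_policy="random")

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=10, allow_nan=False),
                    min_size=11, max_size=11))
    def test_ranking_is_permutation_with_prefix_property(self, scores):
        vocab = fv.default_vocabulary()
        s = np.array(scores)
        pred = fv.rank_fluids(s, vocab)
        assert sorted(pred.order) == list(vocab.numbers)
        # nonincreasing scores aligned with s => every prefix holds the
        # k largest values, and sorted_scores[r] is the score of order[r]
        assert list(pred.sorted_scores) == sorted(s, reverse=True)
        for rank, fluid in enumerate(pred.order):
            assert pred.sorted_scores[rank] == s[vocab.index_of(fluid)]


class TestNeighborCounts:
    def test_worked_example_overlap_and_complement(self, vocab, pgrp):
        net, ann = pgrp
        assert fv.count_neighbors_with_any("O75594", net, ann, {6, 7, 11}) == 20
        neighbors = [t for t in net.neighbors("O75594") if t in ann]
        disjoint = [t for t in neighbors if not (ann.labels(t) & {6, 7, 11})]
        assert sorted(disjoint) == ["P05814", "P07492", "Q13410"]

    def test_empty_fluid_set(self, vocab, pgrp):
        net, ann = pgrp
        assert fv.count_neighbors_with_any("O75594", net, ann, set()) == 0


class TestAnnotationMatrix:
    def test_indicator_rows_and_column_sums(self, vocab, pgrp):
        net, ann = pgrp
        A = fv.build_annotation_matrix(ann, ann.proteins, vocab)
        i = ann.proteins.index("O75594")
        assert set(np.flatnonzero(A[i])) == {vocab.index_of(f) for f in (6, 7, 11)}
        assert list(A.sum(axis=1)) == [ann.m(p) for p in ann.proteins]
        # 18 of the 23 neighbors list plasma/serum
        neighbors = [p for p in ann.proteins if p != "O75594"]
        An = fv.build_annotation_matrix(ann, neighbors, vocab)
        assert An[:, vocab.index_of(6)].sum() == 18

    def test_all_fluids_gives_all_ones_row(self, vocab):
        ann = fv.AnnotationTable({"P": set(range(1, 12))})
        A = fv.build_annotation_matrix(ann, ["P"], vocab)
        assert A.sum() == 11

    def test_unannotated_protein_rejected(self, vocab, pgrp):
        _, ann = pgrp
        with pytest.raises(KeyError):
            fv.build_annotation_matrix(ann, ["NOPE"], vocab)
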