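"""IC, MICA similarity and best-match combiners against enumeration oracles."""

import math

import numpy as np
import pytest

from pleioband.ontosim import (
    OntologyDAG,
    SimilarityMatrix,
    compute_ic,
    entity_similarity,
    pairwise_entity_similarity,
    similarity_partner_counts,
    term_similarity,
)
from pleioband.synthdata import SimConfig, simulate_ontology


def make_dag(edges, annotations):
    terms = frozenset(t for e in edges for t in e)
    return OntologyDAG(
        terms=terms,
        edges=tuple(edges),
        direct_annotations={e: frozenset(ts) for e, ts in annotations.items()},
    )


@pytest.fixture
def toy_dag():
    #        root
    #       /    \
    #      a      b
    #     / \      \
    #    c   d      e
    edges = [("a", "root"), ("b", "root"), ("c", "a"), ("d", "a"), ("e", "b")]
    annotations = {
        "e1": {"c"}, "e2": {"d"}, "e3": {"e"}, "e4": {"a"}, "e5": {"c", "e"},
    }
    return make_dag(edges, annotations)


class TestDagValidation:
    def test_cycle_is_fatal(self):
        with pytest.raises(ValueError, match="cycle"):
            make_dag([("a", "b"), ("b", "a")], {"e": {"a"}})

    def test_multiple_roots_fatal(self):
        with pytest.raises(ValueError, match="root"):
            make_dag([("a", "r1"), ("b", "r2")], {"e": {"a"}})

    def test_unknown_annotation_term_fatal(self):
        with pytest.raises(ValueError, match="unknown terms"):
            make_dag([("a", "root")], {"e": {"zzz"}})


class TestInformationContent:
    def test_root_has_zero_ic(self, toy_dag):
        ic = compute_ic(toy_dag)
        assert ic["root"] == 0.0

    def test_leaf_annotated_by_one_of_ten(self):
        edges = [(f"leaf{i}", "root") for i in range(10)]
        annotations = {f"e{i}": {f"leaf{i}"} for i in range(10)}
        ic = compute_ic(make_dag(edges, annotations))
        assert ic["leaf0"] == pytest.approx(1.0)  # -log10(1/10)

    def test_propagated_counts_match_ancestor_closure(self, toy_dag):
        ic = compute_ic(toy_dag)
        # 'a' covers e1 (c), e2 (d), e4 (a), e5 (c) -> 4 of 5 entities
        assert ic["a"] == pytest.approx(-math.log10(4 / 5))
        # 'b' covers e3 and e5 through e -> 2 of 5
        assert ic["b"] == pytest.approx(-math.log10(2 / 5))

    def test_ic_monotone_child_to_parent(self):
        edges, annotations, _, _ = simulate_ontology(SimConfig(seed=3))
        dag = make_dag(edges, annotations)
        ic = compute_ic(dag)
        for child, parent in edges:
            if math.isfinite(ic[child]):
                assert ic[child] >= ic[parent] - 1e-12

    def test_no_annotations_fatal(self):
        dag = make_dag([("a", "root")], {"e": {"a"}})
        dag.direct_annotations = {}
        with pytest.raises(ValueError, match="no annotated"):
            compute_ic(dag)


class TestTermSimilarity:
    def test_self_similarity_is_one(self, toy_dag):
        ic = compute_ic(toy_dag)
        assert term_similarity("c", "c", toy_dag, ic) == pytest.approx(1.0)

    def test_root_only_common_ancestor_gives_zero(self, toy_dag):
        ic = compute_ic(toy_dag)
        assert term_similarity("c", "e", toy_dag, ic) == 0.0

    def test_mica_matches_exhaustive_scan(self, toy_dag):
        ic = compute_ic(toy_dag)
        # exhaustive: common ancestors of c and d are {a, root}; max IC is a
        mica_ic = max(ic["a"], ic["root"])
        expected = 2 * mica_ic / (ic["c"] + ic["d"])
        assert term_similarity("c", "d", toy_dag, ic) == pytest.approx(expected)

    def test_raw_resnik_flag(self, toy_dag):
        ic = compute_ic(toy_dag)
        assert term_similarity("c", "d", toy_dag, ic, normalize=False) == \
            pytest.approx(ic["a"])

    def test_unknown_term_fatal(self, toy_dag):
        ic = compute_ic(toy_dag)
        with pytest.raises(ValueError, match="unknown term"):
            term_similarity("c", "nope", toy_dag, ic)


class TestEntitySimilarity:
    def test_identical_profiles_score_one_under_bma(self, toy_dag):
        ic = compute_ic(toy_dag)
        assert entity_similarity("e5", "e5", toy_dag, ic) == pytest.approx(1.0)

    def test_root_level_only_overlap_scores_zero(self, toy_dag):
        ic = compute_ic(toy_dag)
        assert entity_similarity("e1", "e3", toy_dag, ic, "maximum") == 0.0

    def test_hand_enumerated_asymmetric_profiles(self, toy_dag):
        ic = compute_ic(toy_dag)
        # e5={c,e} vs e2={d}: matrix is [sim(c,d)], [sim(e,d)]
        s_cd = term_similarity("c", "d", toy_dag, ic)
        s_ed = term_similarity("e", "d", toy_dag, ic)
        best = [s_cd, s_ed, max(s_cd, s_ed)]  # best match per row (c, e) and column (d)
        assert entity_similarity("e5", "e2", toy_dag, ic, "maximum") == \
            pytest.approx(max(s_cd, s_ed))
        assert entity_similarity("e5", "e2", toy_dag, ic, "complete") == \
            pytest.approx(min(best))
        assert entity_similarity("e5", "e2", toy_dag, ic) == \
            pytest.approx(sum(best) / 3)

    def test_unannotated_entity_fatal(self, toy_dag):
        ic = compute_ic(toy_dag)
        with pytest.raises(ValueError, match="ghost"):
            entity_similarity("ghost", "e1", toy_dag, ic)

    @pytest.mark.parametrize("seed", range(12))
    def test_combiner_bounds_and_symmetry_on_random_dags(self, seed):
        edges, annotations, _, _ = simulate_ontology(SimConfig(seed=seed))
        dag = make_dag(edges, annotations)
        ic = compute_ic(dag)
        entities = sorted(annotations)
        for i, e1 in enumerate(entities):
            for e2 in entities[i:]:
                comp = entity_similarity(e1, e2, dag, ic, "complete")
                bma = entity_similarity(e1, e2, dag, ic, "best-match-average")
                mx = entity_similarity(e1, e2, dag, ic, "maximum")
                assert 0.0 <= comp <= bma + 1e-12 <= mx + 1e-12 <= 1.0 + 1e-12
                assert bma == pytest.approx(
                    entity_similarity(e2, e1, dag, ic, "best-match-average"))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_truth(self, seed):
        edges, annotations, truth_ic, truth_sims = simulate_ontology(SimConfig(seed=seed))
        dag = make_dag(edges, annotations)
        ic = compute_ic(dag)
        for t, v in truth_ic.items():
            if math.isfinite(v):
                assert ic[t] == pytest.approx(v, abs=1e-9)
            else:
                assert math.isinf(ic[t])
        for (e1, e2, combine), v in truth_sims.items():
            assert entity_similarity(e1, e2, dag, ic, combine) == \
                pytest.approx(v, abs=1e-9)


class TestChainDag:
    def test_mica_is_the_shallower_term_on_a_chain(self):
        edges = [("t1", "t0"), ("t2", "t1"), ("t3", "t2")]
        annotations = {"e0": {"t0"}, "e1": {"t1"}, "e2": {"t2"}, "e3": {"t3"}}
        dag = make_dag(edges, annotations)
        ic = compute_ic(dag)
        # on a chain, the common ancestors of ti and tj form the shallower
        # term's closure, so MICA is the shallower (less informative) term
        assert term_similarity("t1", "t3", dag, ic, normalize=False) == \
            pytest.approx(ic["t1"])
        assert term_similarity("t2", "t3", dag, ic, normalize=False) == \
            pytest.approx(ic["t2"])


class TestPartnerCounts:
    def test_all_pairwise_high(self):
        m = SimilarityMatrix(["a", "b", "c"], np.full((3, 3), 0.9))
        counts, qualifying = similarity_partner_counts(m, 0.5, 2)
        assert counts == {"a": 2, "b": 2, "c": 2}
        assert qualifying == ["a", "b", "c"]

    def test_identity_matrix_has_no_partners(self):
        m = SimilarityMatrix(["a", "b"], np.eye(2))
        counts, qualifying = similarity_partner_counts(m, 0.5, 1)
        assert counts == {"a": 0, "b": 0} and qualifying == []

    def test_threshold_is_strict(self):
        scores = np.array([[1.0, 0.5], [0.5, 1.0]])
        counts, _ = similarity_partner_counts(SimilarityMatrix(["a", "b"], scores), 0.5, 0)
        assert counts == {"a": 0, "b": 0}

    def test_counts_match_double_loop_recount(self):
        rng = np.random.default_rng(11)
        raw = rng.random((10, 10))
        scores = (raw + raw.T) / 2
        np.fill_diagonal(scores, 1.0)
        entities = [f"e{i}" for i in range(10)]
        counts, _ = similarity_partner_counts(SimilarityMatrix(entities, scores), 0.5, 5)
        for i, e in enumerate(entities):
            expected = sum(
                1 for j in range(10) if j != i and scores[i, j] > 0.5
            )
            assert counts[e] == expected

    def test_counts_invariant_to_entity_ordering(self):
        rng = np.random.default_rng(5)
        raw = rng.random((6, 6))
        scores = (raw + raw.T) / 2
        entities = [f"e{i}" for i in range(6)]
        counts1, _ = similarity_partner_counts(SimilarityMatrix(entities, scores), 0.4, 0)
        perm = [3, 1, 5, 0, 4, 2]
        counts2, _ = similarity_partner_counts(
            SimilarityMatrix([entities[i] for i in perm], scores[np.ix_(perm, perm)]),
            0.4, 0,
        )
        assert counts1 == counts2


def test_pairwise_matrix_is_symmetric_with_unit_diagonal(toy_dag):
    ic = compute_ic(toy_dag)
    m = pairwise_entity_similarity(toy_dag, ic)
    assert np.allclose(m.scores, m.scores.T)
    assert np.allclose(np.diag(m.scores), 1.0)
    assert ((m.scores >= 0) & (m.scores <= 1 + 1e-12)).all()
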