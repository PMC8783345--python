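"""Hypergeometric over-representation, BH correction, simRel and Venn logic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesiclink.enrichment import (bh_adjust, hypergeometric_enrich,
                                  propagate_annotations, reduce_terms, simrel,
                                  term_probabilities, venn_partition)
from vesiclink.errors import VesiclinkError
from vesiclink.io import GoAnnotation, GoDag, GoTerm
from vesiclink.simulate import gen_go


def mini_dag(edges, namespace="biological_process"):
    """Build a GoDag from {child: [parents]} (keys+values define the terms)."""
    ids = set(edges) | {p for ps in edges.values() for p in ps}
    return GoDag({t: GoTerm(t, t, namespace, frozenset(edges.get(t, ())))
                  for t in ids})


class TestPropagate:
    def test_linear_closure(self):
        dag = mini_dag({"t": ["p"], "p": ["root"]})
        out = propagate_annotations([GoAnnotation("g", "t")], dag)
        assert out["g"] == {"t", "p", "root"}

    def test_diamond(self):
        dag = mini_dag({"t": ["p1", "p2"], "p1": ["root"], "p2": ["root"]})
        out = propagate_annotations([GoAnnotation("g", "t")], dag)
        assert out["g"] == {"t", "p1", "p2", "root"}

    def test_idempotent_on_closed_input(self):
        dag = mini_dag({"t": ["root"]})
        anns = [GoAnnotation("g", "t"), GoAnnotation("g", "root")]
        assert propagate_annotations(anns, dag)["g"] == {"t", "root"}

    def test_unknown_term_skipped(self):
        dag = mini_dag({"t": ["root"]})
        out = propagate_annotations(
            [GoAnnotation("g", "t"), GoAnnotation("g", "GHOST")], dag)
        assert out["g"] == {"t", "root"}


def exact_tail(N, K, n, k):
    """Independent exact enumeration of the hypergeometric upper tail."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / total


class TestHypergeometric:
    def _run(self, target, background, gene2terms, **kw):
        return hypergeometric_enrich(set(target), set(background), gene2terms,
                                     **kw)

    def test_exact_derived_example(self):
        # N=20, K=5, n=8, k=4 -> 7280/125970
        background = [f"g{i}" for i in range(20)]
        annotated = background[:5]
        gene2terms = {g: {"T"} for g in annotated}
        target = annotated[:4] + background[5:9]
        (res,) = self._run(target, background, gene2terms)
        assert res.k == 4 and res.K == 5 and res.n == 8 and res.N == 20
        assert res.p_value == pytest.approx(7280 / 125970, abs=1e-12)

    def test_terms_with_zero_target_hits_skipped(self):
        background = [f"g{i}" for i in range(10)]
        gene2terms = {"g9": {"T"}}
        assert self._run(background[:3], background, gene2terms) == []

    def test_target_equals_background_degenerate_p_one(self):
        background = [f"g{i}" for i in range(10)]
        gene2terms = {g: {"T"} for g in background[:4]}
        (res,) = self._run(background, background, gene2terms)
        assert res.p_value == pytest.approx(1.0)

    def test_target_outside_background_raises(self):
        with pytest.raises(VesiclinkError, match="alien"):
            self._run({"alien"}, {"g1"}, {})

    def test_matches_exact_enumeration_grid(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            N = int(rng.integers(8, 51))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            background = [f"g{i}" for i in range(N)]
            annotated = set(rng.choice(background, size=K, replace=False))
            target = set(rng.choice(background, size=n, replace=False))
            k = len(target & annotated)
            if k == 0:
                continue
            gene2terms = {g: {"T"} for g in annotated}
            (res,) = self._run(target, background, gene2terms)
            assert res.p_value == pytest.approx(exact_tail(N, K, n, k),
                                                abs=1e-12)

    def test_matches_permutation_oracle(self):
        # resample target sets of the same size and compare tail frequencies
        rng = np.random.default_rng(12)
        N, K, n = 40, 12, 10
        background = [f"g{i}" for i in range(N)]
        annotated = set(background[:K])
        target = set(background[5:5 + n])
        k = len(target & annotated)
        gene2terms = {g: {"T"} for g in annotated}
        (res,) = self._run(target, background, gene2terms)

        reps = 20000
        indicator = np.zeros(N)
        indicator[:K] = 1
        draws = np.random.default_rng(99).random((reps, N)).argpartition(
            n, axis=1)[:, :n]
        ks = indicator[draws].sum(axis=1)
        p_hat = float((ks >= k).mean())
        se = math.sqrt(p_hat * (1 - p_hat) / reps)
        assert abs(res.p_value - p_hat) <= 3 * se + 1e-9


class TestBH:
    def test_hand_computed_example(self):
        q = bh_adjust([0.001, 0.01, 0.02, 0.8])
        assert q == pytest.approx([0.004, 0.02, 0.02667, 0.8], abs=1e-4)

    def test_single_and_equal_p(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_q_geq_p_and_monotone_along_sorted_p(self, ps):
        q = np.array(bh_adjust(ps))
        p = np.array(ps)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestSimrel:
    def test_identity_value_is_one_minus_p(self):
        dag = mini_dag({"t": ["root"]})
        prob = {"t": 0.01, "root": 1.0}
        assert simrel("t", "t", dag, prob) == pytest.approx(0.99)

    def test_root_only_common_ancestor_scores_zero(self):
        dag = mini_dag({"a": ["root"], "b": ["root"]})
        prob = {"a": 0.1, "b": 0.2, "root": 1.0}
        assert simrel("a", "b", dag, prob) == 0.0

    def test_symmetry_and_range_on_random_dags(self):
        sim = gen_go([f"g{i}" for i in range(60)], n_terms=25, seed=8)
        gene2terms = propagate_annotations(sim.annotations, sim.dag)
        prob = term_probabilities(set(gene2terms), gene2terms)
        terms = sorted(prob)
        rng = np.random.default_rng(4)
        for _ in range(40):
            t1, t2 = rng.choice(terms, size=2)
            s12 = simrel(t1, t2, sim.dag, prob)
            s21 = simrel(t2, t1, sim.dag, prob)
            assert s12 == pytest.approx(s21)
            assert 0.0 <= s12 <= 1.0


def _fake_result(term, p):
    from vesiclink.enrichment import EnrichmentResult
    return EnrichmentResult(term, term, "biological_process", 1, 1, 1, 10,
                            p, p, True)


class TestReduceTerms:
    def test_identical_annotation_terms_cluster_together(self):
        dag = mini_dag({"a": ["root"], "b": ["a"]})
        prob = {"a": 0.1, "b": 0.1, "root": 1.0}
        # simrel(a,b) via common ancestor a: (2*IC(a))/(IC(a)+IC(b))*(1-0.1)=0.9
        clusters = reduce_terms([_fake_result("a", 1e-5),
                                 _fake_result("b", 1e-4)], dag, prob,
                                threshold=0.7)
        assert len(clusters) == 1
        assert clusters[0].representative == "a"
        assert clusters[0].members == ("a", "b")

    def test_root_only_related_terms_stay_separate(self):
        dag = mini_dag({"a": ["root"], "b": ["root"]})
        prob = {"a": 0.1, "b": 0.1, "root": 1.0}
        clusters = reduce_terms([_fake_result("a", 1e-5),
                                 _fake_result("b", 1e-4)], dag, prob)
        assert [c.representative for c in clusters] == ["a", "b"]

    def test_threshold_one_gives_all_singletons(self):
        dag = mini_dag({"a": ["root"], "b": ["a"]})
        prob = {"a": 0.1, "b": 0.1, "root": 1.0}
        clusters = reduce_terms([_fake_result("a", 1e-5),
                                 _fake_result("b", 1e-4)], dag, prob,
                                threshold=1.0)
        assert all(len(c.members) == 1 for c in clusters)

    def test_clusters_partition_the_enriched_set(self):
        sim = gen_go([f"g{i}" for i in range(80)], n_terms=20, seed=3)
        gene2terms = propagate_annotations(sim.annotations, sim.dag)
        prob = term_probabilities(set(gene2terms), gene2terms)
        results = [_fake_result(t, 10 ** -(i + 3))
                   for i, t in enumerate(sorted(prob))]
        clusters = reduce_terms(results, sim.dag, prob)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(r.term_id for r in results)


class TestVenn:
    def test_two_set_example(self):
        part = venn_partition({"A": {1, 2}, "B": {2, 3}})
        assert part == {"A": (1, [1]), "A&B": (1, [2]), "B": (1, [3])}

    def test_disjoint_sets_only_singleton_signatures(self):
        part = venn_partition({"A": {1}, "B": {2}, "C": {3}})
        assert set(part) == {"A", "B", "C"}

    def test_identical_sets_single_full_signature(self):
        sets = {c: {1, 2, 3} for c in "ABCDE"}
        part = venn_partition(sets)
        assert list(part) == ["A&B&C&D&E"]
        assert part["A&B&C&D&E"][0] == 3

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(6)
        sets = {f"S{i}": set(rng.choice(50, size=rng.integers(0, 30),
                                        replace=False).tolist())
                for i in range(4)}
        part = venn_partition(sets)
        assert sum(c for c, _ in part.values()) == len(set().union(*sets.values()))

    def test_set_count_bounds(self):
        with pytest.raises(VesiclinkError):
            venn_partition({"A": {1}})
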