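"""Unit tests for the over-representation engine.

The hypergeometric tail is checked against an exhaustive combinatorial
enumeration (all n-subsets of an N-set, N small), and the BH adjustment
against a hand-written step-up implementation — both oracles are
independent of the code paths they validate.
"""

from itertools import combinations

import numpy as np
import pytest

from herbnet.enrichment import (
    GO_BP,
    PATHWAY,
    AnnotationTerm,
    bh_adjust,
    enrich,
    hypergeometric_tail,
    select_terms,
)
from herbnet.errors import ValidationError


def enumeration_tail(k: int, K: int, n: int, N: int) -> float:
    """Oracle: exact P(overlap >= k) by enumerating every n-subset."""
    marked = set(range(K))
    total = hits = 0
    for subset in combinations(range(N), n):
        total += 1
        if len(marked.intersection(subset)) >= k:
            hits += 1
    return hits / total


def step_up_oracle(pvals):
    """Oracle: textbook BH step-up, written independently."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_top)
        adj[i] = min(running_min, 1.0)
    return adj


def make_terms(gene_sets, kind=GO_BP):
    return [
        AnnotationTerm(f"T{i:03d}", f"term {i}", kind, frozenset(gs))
        for i, gs in enumerate(gene_sets)
    ]


class TestHypergeometricTail:
    def test_zero_overlap_tail_is_one(self):
        assert hypergeometric_tail(0, 5, 3, 20) == 1.0
        assert hypergeometric_tail(0, 0, 0, 1) == 1.0

    def test_degenerate_certainty(self):
        assert hypergeometric_tail(4, 4, 4, 4) == pytest.approx(1.0)

    @pytest.mark.parametrize("N", [1, 4, 8])
    def test_matches_enumeration_small_universes(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeometric_tail(k, K, n, N) == pytest.approx(
                        enumeration_tail(k, K, n, N), abs=1e-12
                    )

    def test_nonincreasing_in_k(self):
        K, n, N = 30, 40, 100
        tails = [hypergeometric_tail(k, K, n, N) for k in range(min(K, n) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_tail(5, 4, 10, 20)  # k > K
        with pytest.raises(ValidationError):
            hypergeometric_tail(0, 30, 10, 20)  # K > N
        with pytest.raises(ValidationError):
            hypergeometric_tail(0, 0, 0, 0)  # empty universe


class TestBHAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40)).tolist()
            assert bh_adjust(p) == pytest.approx(step_up_oracle(p), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.random(25)
        adj = bh_adjust(p)
        perm = rng.permutation(25)
        assert bh_adjust(p[perm]) == pytest.approx(adj[perm])

    def test_dominates_raw_and_capped(self):
        rng = np.random.default_rng(9)
        p = rng.random(40)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestEnrich:
    def test_exact_match_term_ranks_first(self):
        hit_genes = {f"g{i}" for i in range(10)}
        decoys = {f"d{i}" for i in range(100)}
        universe = hit_genes | decoys
        terms = make_terms([hit_genes, set(list(decoys)[:10]),
                            set(list(decoys)[10:30])])
        results = enrich(hit_genes, terms, universe)
        assert results[0].term.genes == frozenset(hit_genes)
        assert results[0].k == 10

    def test_disjoint_query_gives_no_results(self):
        terms = make_terms([{"a", "b"}])
        assert enrich({"x"}, terms, {"a", "b", "x"}) == []

    def test_full_universe_query_p_raw_one(self):
        universe = {f"g{i}" for i in range(30)}
        terms = make_terms([set(list(universe)[:5]), set(list(universe)[5:12])])
        for r in enrich(set(universe), terms, universe):
            assert r.p_raw == pytest.approx(1.0)

    def test_query_clipped_to_universe(self, caplog):
        universe = {"a", "b", "c"}
        terms = make_terms([{"a", "b"}])
        results = enrich({"a", "z"}, terms, universe)
        assert results[0].n == 1  # 'z' clipped

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            enrich({"a"}, [], set())

    def test_bh_applied_within_kind(self):
        universe = {f"g{i}" for i in range(50)}
        genes = set(list(universe)[:10])
        go = make_terms([genes], kind=GO_BP)
        pw = make_terms([genes], kind=PATHWAY)
        results = enrich(genes, go + pw, universe)
        # each kind has a single tested term: adjusted == raw in both
        for r in results:
            assert r.p_adj == pytest.approx(r.p_raw)

    def test_sorted_and_adj_dominates(self):
        rng = np.random.default_rng(2)
        universe = {f"g{i}" for i in range(200)}
        pool = sorted(universe)
        terms = make_terms(
            [set(rng.choice(pool, size=20, replace=False)) for _ in range(30)]
        )
        query = set(rng.choice(pool, size=40, replace=False))
        results = enrich(query, terms, universe)
        adj = [r.p_adj for r in results]
        assert adj == sorted(adj)
        assert all(r.p_adj >= r.p_raw - 1e-15 for r in results)


class TestSelectTerms:
    def _results(self, n, k_of=lambda i: 10, p_of=lambda i: 0.001):
        universe = {f"g{i}" for i in range(1000)}
        out = []
        for i in range(n):
            t = AnnotationTerm(f"P{i:03d}", f"pathway {i}", PATHWAY,
                               frozenset(list(universe)[:20]))
            from herbnet.enrichment import EnrichmentResult

            out.append(EnrichmentResult(t, k_of(i), 20, 50, 1000,
                                        p_of(i), p_of(i)))
        return out

    def test_top_n_cap(self):
        results = self._results(60)
        assert len(select_terms(results, p_max=0.05, top_n=40)) == 40

    def test_fewer_passing_than_top_n(self):
        results = self._results(5)
        assert len(select_terms(results, p_max=0.05, top_n=40)) == 5

    def test_strict_p_cut(self):
        results = self._results(3, p_of=lambda i: 0.05)
        assert select_terms(results, p_max=0.05) == []

    def test_tie_break_lexicographic(self):
        results = self._results(4)
        picked = select_terms(results, p_max=0.05, top_n=2)
        assert [r.term.term_id for r in picked] == ["P000", "P001"]

    def test_negative_top_n_rejected(self):
        with pytest.raises(ValidationError):
            select_terms([], p_max=0.05, top_n=-1)
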