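"""Term filtering, multiple-testing adjustment, and pipeline orchestration."""

from fractions import Fraction

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from circannot import (
    AnnotationTerm,
    adjust_pvalues,
    annotate_circrna,
    filter_terms,
)
from circannot.synthetic import SyntheticSpec, random_instance

from conftest import exhaustive_null, exhaustive_pvalue


def term_of_size(n_mu_total, n_m_total, k_mu, k_m, tid="T"):
    g_mu = np.zeros(n_mu_total, dtype=int)
    g_m = np.zeros(n_m_total, dtype=int)
    g_mu[:k_mu] = 1
    g_m[:k_m] = 1
    return AnnotationTerm(term_id=tid, g_mu=g_mu, g_m=g_m)


class TestFilterTerms:
    def test_inclusive_bounds(self):
        sizes = [9, 10, 1000, 1001]
        terms = [term_of_size(2, 1200, 0, s, tid=f"T{s}") for s in sizes]
        kept = filter_terms(terms)
        assert [t.size for t in kept] == [10, 1000]

    def test_trivial_window_is_identity(self):
        terms = [term_of_size(3, 5, 1, s) for s in range(5)]
        assert filter_terms(terms, 0, 10**9) == terms

    def test_matches_hand_filter(self):
        rng = np.random.default_rng(0)
        terms = []
        for i in range(10):
            k_m = int(rng.integers(0, 8))
            terms.append(term_of_size(2, 8, 0, k_m, tid=f"T{i}"))
        kept = filter_terms(terms, 3, 5)
        assert kept == [t for t in terms if 3 <= t.size <= 5]

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            filter_terms([], 5, 3)


class TestAdjustPvalues:
    def test_single_test_unchanged(self):
        for method in ("bonferroni", "holm", "bh"):
            assert adjust_pvalues([Fraction(1, 100)], method) == [Fraction(1, 100)]

    def test_bonferroni_by_hand(self):
        p = [Fraction(1, 100), Fraction(4, 100), Fraction(3, 100)]
        assert adjust_pvalues(p, "bonferroni") == [
            Fraction(3, 100),
            Fraction(12, 100),
            Fraction(9, 100),
        ]

    def test_bh_step_up_by_hand(self):
        p = [Fraction(1, 100), Fraction(2, 100), Fraction(3, 100), Fraction(1, 2)]
        assert adjust_pvalues(p, "bh") == [
            Fraction(4, 100),
            Fraction(4, 100),
            Fraction(4, 100),
            Fraction(1, 2),
        ]

    @pytest.mark.parametrize("method,sm_method", [
        ("bonferroni", "bonferroni"),
        ("holm", "holm"),
        ("bh", "fdr_bh"),
    ])
    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_statsmodels(self, method, sm_method, seed):
        rng = np.random.default_rng(seed)
        p = [Fraction(int(x), 10_000) for x in rng.integers(1, 10_000, size=12)]
        ours = [float(x) for x in adjust_pvalues(p, method)]
        theirs = multipletests([float(x) for x in p], method=sm_method)[1]
        np.testing.assert_allclose(ours, theirs, rtol=1e-12)

    def test_empty_vector(self):
        assert adjust_pvalues([], "holm") == []

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([Fraction(0)], "bh")

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown"):
            adjust_pvalues([Fraction(1, 2)], "sidak")


class TestAnnotateCircrna:
    def test_worked_example_row(self, example):
        graph, term, _ = example
        rows = annotate_circrna(graph, "circ-1", [term], min_size=1, max_size=100)
        assert len(rows) == 1
        r = rows[0]
        assert r.s == 8
        assert r.expected == Fraction(37, 5)
        assert r.ratio == Fraction(40, 37)
        assert r.p == Fraction(1, 2)
        assert r.p_bonferroni == r.p_fdr == Fraction(1, 2)

    def test_unknown_circ_id(self, example):
        graph, term, _ = example
        with pytest.raises(KeyError):
            annotate_circrna(graph, "ghost", [term])

    def test_empty_family_after_filter_warns(self, example, caplog):
        graph, term, _ = example
        with caplog.at_level("WARNING"):
            rows = annotate_circrna(graph, "circ-1", [term], min_size=100)
        assert rows == []
        assert any("no terms" in m for m in caplog.messages)

    def test_disconnected_circrna_all_p_one(self):
        """A circRNA without miRNA partners cannot be enriched for anything."""
        spec = SyntheticSpec(
            n_mirna=10, n_mrna=30, circ_degree=0.0, mirna_mrna_density=0.2,
            n_terms=8, term_size_range=(4, 10), seed=5,
        )
        graph, terms = random_instance(spec)
        rows = annotate_circrna(graph, "circ-1", terms, min_size=1, max_size=100)
        assert rows and all(r.p == 1 for r in rows)
        assert all(r.s == 0 for r in rows)

    def test_p_column_matches_exhaustive_oracle(self):
        spec = SyntheticSpec(
            n_mirna=5, n_mrna=7, circ_degree=0.6, mirna_mrna_density=0.4,
            n_terms=5, term_size_range=(2, 6), seed=11,
        )
        graph, terms = random_instance(spec)
        rows = annotate_circrna(graph, "circ-1", terms, min_size=1, max_size=100)
        nb_a = graph.circ_mirna[0]
        w_m = graph.mirna_mrna @ nb_a
        by_id = {t.term_id: t for t in terms}
        for r in rows:
            t = by_id[r.term_id]
            oracle = exhaustive_null(nb_a, w_m, t.k_mu, t.k_m)
            assert r.p == exhaustive_pvalue(oracle, r.s)
        assert [r.p for r in rows] == sorted(r.p for r in rows)

    def test_term_order_invariance(self):
        spec = SyntheticSpec(
            n_mirna=6, n_mrna=10, circ_degree=0.5, mirna_mrna_density=0.3,
            n_terms=6, term_size_range=(2, 8), seed=3,
        )
        graph, terms = random_instance(spec)
        fwd = annotate_circrna(graph, "circ-1", terms, min_size=1, max_size=100)
        rev = annotate_circrna(graph, "circ-1", terms[::-1], min_size=1, max_size=100)
        key = lambda rows: {
            r.term_id: (r.p, r.p_bonferroni, r.p_holm, r.p_fdr) for r in rows
        }
        assert key(fwd) == key(rev)

    def test_mc_column_present_and_seeded(self, example):
        graph, term, _ = example
        rows = annotate_circrna(
            graph, "circ-1", [term], min_size=1, max_size=100,
            mc_trials=2000, seed=9,
        )
        again = annotate_circrna(
            graph, "circ-1", [term], min_size=1, max_size=100,
            mc_trials=2000, seed=9,
        )
        assert rows[0].p_mc is not None
        assert rows[0].p_mc == again[0].p_mc

    def test_exactness_of_tail_count(self, example):
        """p * total is the integer upper-tail count of the null."""
        graph, term, _ = example
        r = annotate_circrna(graph, "circ-1", [term], min_size=1, max_size=100)[0]
        assert r.p * 30 == 15
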