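"""Triplet likelihoods, the clock vs free LRT and FDR adjustment."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from dupreloc.likelihood import (
    aa_log_likelihood,
    aa_site_likelihoods,
    clock_test,
    clock_test_cohort,
    compress_patterns,
    fdr_adjust,
    fit_triplet_aa,
    lrt,
)
from dupreloc.simulate import TripletAlignment, TripletTree, simulate_aa_triplet


class TestPruning:
    def test_all_one_site_patterns_match_enumeration(self, jtt):
        """Pruning equals the exhaustive sum over all 20 internal states,
        checked simultaneously for all 8000 possible triplet patterns with
        matrix-exponential transition matrices as the oracle."""
        b = (0.07, 0.19, 0.42)
        pmats = [expm(jtt.rate_matrix * t) for t in b]
        expected = np.einsum("s,si,sj,sk->ijk", jtt.freqs, *pmats)
        idx = np.array(list(itertools.product(range(20), repeat=3)))
        got = aa_site_likelihoods(
            (idx[:, 0], idx[:, 1], idx[:, 2], np.ones(len(idx))), jtt, b)
        # the two routes use different matrix-exponential algorithms, so
        # agreement is limited only by floating-point roundoff
        assert np.allclose(got, expected.ravel(), rtol=1e-9, atol=1e-300)

    def test_zero_branch_single_site_is_log_pi(self, jtt):
        aln = TripletAlignment(("a", "b", "c"), ("A", "A", "A"))
        got = aa_log_likelihood(aln, TripletTree(0, 0, 0), jtt)
        assert got == pytest.approx(np.log(jtt.freqs[0]), abs=1e-12)

    def test_long_branch_limit_is_product_of_frequencies(self, jtt):
        aln = TripletAlignment(("a", "b", "c"), ("A", "R", "V"))
        got = aa_log_likelihood(aln, TripletTree(50, 50, 50), jtt)
        expected = np.log(jtt.freqs[0] * jtt.freqs[1] * jtt.freqs[19])
        assert got == pytest.approx(expected, abs=1e-6)

    def test_invariant_under_leaf_relabelling(self, jtt):
        aln = simulate_aa_triplet(TripletTree(0.1, 0.2, 0.3), jtt, 300, seed=2)
        swapped = TripletAlignment(aln.ids, (aln.seqs[1], aln.seqs[0], aln.seqs[2]))
        l1 = aa_log_likelihood(aln, TripletTree(0.1, 0.2, 0.3), jtt)
        l2 = aa_log_likelihood(swapped, TripletTree(0.2, 0.1, 0.3), jtt)
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_gaps_marginalized_as_missing(self, jtt):
        full = TripletAlignment(("a", "b", "c"), ("AR", "AR", "AR"))
        gapped = TripletAlignment(("a", "b", "c"), ("A-", "AR", "AR"))
        tree = TripletTree(0.1, 0.1, 0.1)
        # the gapped column marginalizes d1: its site likelihood is the
        # 2-leaf likelihood, always >= the 3-leaf one
        assert aa_log_likelihood(gapped, tree, jtt) > \
            aa_log_likelihood(full, tree, jtt)

    def test_empty_alignment_raises(self, jtt):
        with pytest.raises(ValueError):
            compress_patterns(TripletAlignment(("a", "b", "c"), ("", "", "")))


class TestFits:
    def test_identical_sequences_give_zero_branches(self, jtt):
        aln = TripletAlignment(("a", "b", "c"), ("MKVAW" * 20,) * 3)
        free_tree, lnl_free = fit_triplet_aa(aln, "free", jtt)
        clock_tree, lnl_clock = fit_triplet_aa(aln, "clock", jtt)
        assert max(free_tree.lengths) < 1e-6
        assert lnl_free == pytest.approx(lnl_clock, abs=1e-6)

    def test_nesting_free_at_least_clock(self, jtt):
        for seed in range(5):
            aln = simulate_aa_triplet(TripletTree(0.15, 0.05, 0.3), jtt,
                                      400, seed=seed)
            _, lnl_free = fit_triplet_aa(aln, "free", jtt, n_starts=2)
            _, lnl_clock = fit_triplet_aa(aln, "clock", jtt, n_starts=2)
            assert lnl_free >= lnl_clock - 1e-6

    def test_recovers_asymmetric_branches(self, jtt):
        aln = simulate_aa_triplet(TripletTree(0.3, 0.1, 0.3), jtt, 2000, seed=11)
        res = clock_test(aln, jtt, n_starts=2)
        assert res.b1 > res.b2
        assert res.lrt.p_value < 0.01

    def test_cohort_assigns_accelerated_copy_after_fdr(self, jtt):
        alignments = {
            f"p{i}": simulate_aa_triplet(TripletTree(0.3, 0.1, 0.3), jtt,
                                         1500, seed=[21, i])
            for i in range(4)
        }
        results = clock_test_cohort(alignments, jtt, n_starts=2)
        for r in results:
            assert r.q_value is not None
            if r.q_value < 0.05:
                assert r.accelerated_copy == "gene1"
            else:
                assert r.accelerated_copy == "none"


class TestLrt:
    def test_equal_likelihoods_give_p_one(self):
        res = lrt(-100.0, -100.0)
        assert res.two_delta_l == 0.0
        assert res.p_value == 1.0

    def test_published_likelihood_pair_arithmetic(self):
        """Alternative -6306.97 vs null -6311.76 gives 2dL = 9.58 and a
        chi-square(1) p of about 0.002."""
        res = lrt(-6306.97, -6311.76)
        assert res.two_delta_l == pytest.approx(9.58, abs=1e-9)
        assert res.p_value == pytest.approx(0.00197, abs=5e-5)

    def test_critical_value(self):
        assert lrt(-99.0, -99.0 - 3.841 / 2).p_value == pytest.approx(0.05, abs=1e-3)

    def test_df_validation(self):
        with pytest.raises(ValueError):
            lrt(-1.0, -2.0, df=0)


class TestFdr:
    def test_single_p_identity(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_worked_example(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_unchanged(self):
        assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_monotone_and_idempotent(self, rng):
        p = rng.uniform(size=30)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0)
        assert fdr_adjust(q)[order][-1] == pytest.approx(q[order][-1])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])
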