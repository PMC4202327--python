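"""Codon-level divergence: back-translation, NG86 and ML dN/dS, asymmetry LRT."""

import warnings

import numpy as np
import pytest

from dupreloc.codonmodels import (
    CodonQ,
    codons_to_indices,
    dn_ds_from_t,
    f3x4_freqs,
    uniform_codon_freqs,
)
from dupreloc.dnds import (
    back_translate_alignment,
    branch_asymmetry_test,
    gap_free_codon_columns,
    ng86_dnds,
    pairwise_dnds_ml,
)
from dupreloc.simulate import TripletTree, simulate_codon_triplet


class TestCodonModel:
    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_transition_rows_sum_to_one(self, t):
        q = CodonQ(2.0, 0.3, tuple(uniform_codon_freqs()))
        p = q.transition_matrix(t)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_dn_ds_decomposition_recovers_omega(self):
        pi = uniform_codon_freqs()
        dn, ds = dn_ds_from_t(0.4, 2.0, 0.3, pi)
        assert dn / ds == pytest.approx(0.3, rel=1e-9)

    def test_stop_codons_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            codons_to_indices("ATGTAA")

    def test_f3x4_sums_to_one(self):
        idx = codons_to_indices("ATGAAACCCGGG")
        pi = f3x4_freqs(idx)
        assert pi.shape == (61,)
        assert pi.sum() == pytest.approx(1.0)


class TestBackTranslation:
    def test_gap_expansion(self):
        out = back_translate_alignment({"x": "M-K"}, {"x": "ATGAAA"})
        assert out == {"x": "ATG---AAA"}

    def test_terminal_stop_stripped(self):
        out = back_translate_alignment({"x": "MK"}, {"x": "ATGAAATAA"})
        assert out == {"x": "ATGAAA"}

    def test_translation_mismatch_names_position(self):
        with pytest.raises(ValueError, match="residue 2"):
            back_translate_alignment({"x": "MW"}, {"x": "ATGAAA"})

    def test_internal_stop_raises(self):
        with pytest.raises(ValueError, match="stop"):
            back_translate_alignment({"x": "M*K"}, {"x": "ATGTAAAAA"})


class TestNg86:
    def test_identical_sequences_zero(self):
        r = ng86_dnds("ATGAAA", "ATGAAA")
        assert r.dn == 0.0 and r.ds == 0.0

    def test_single_synonymous_difference(self):
        # Phe TTT -> TTC is synonymous: Sd=1, Nd=0
        r = ng86_dnds("TTT", "TTC")
        assert r.dn == 0.0
        assert r.ds > 0.0

    def test_stop_codon_in_input_raises(self):
        with pytest.raises(ValueError):
            ng86_dnds("TAAAAA", "TAAAAA")

    def test_matches_biopython_reference(self):
        """Cross-check counting conventions against an independent NG86
        implementation on a simulated pair."""
        aln = simulate_codon_triplet(TripletTree(0.15, 0.15, 0.0), 2.0,
                                     [(1.0, (0.3,) * 3)], n_codons=500, seed=8)
        mine = ng86_dnds(aln.seqs[0], aln.seqs[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
            dn_ref, ds_ref = cal_dn_ds(CodonSeq(aln.seqs[0]),
                                       CodonSeq(aln.seqs[1]), method="NG86")
        assert mine.dn == pytest.approx(dn_ref, abs=1e-9)
        assert mine.ds == pytest.approx(ds_ref, abs=1e-9)


class TestPairwiseMl:
    def test_identical_sequences_zero(self):
        r = pairwise_dnds_ml("ATGAAACCC", "ATGAAACCC")
        assert r.dn == 0.0 and r.ds == 0.0 and r.omega == 0.0

    def test_parameter_recovery(self):
        aln = simulate_codon_triplet(TripletTree(0.15, 0.15, 0.0), 2.0,
                                     [(1.0, (0.2,) * 3)], n_codons=3000, seed=14)
        r = pairwise_dnds_ml(aln.seqs[0], aln.seqs[1])
        assert 0.15 <= r.omega <= 0.25
        assert r.t == pytest.approx(0.3, rel=0.15)

    def test_agrees_with_ng86_at_low_divergence(self):
        for seed in (0, 1):
            aln = simulate_codon_triplet(TripletTree(0.1, 0.1, 0.0), 2.0,
                                         [(1.0, (0.2,) * 3)],
                                         n_codons=1500, seed=seed)
            ml = pairwise_dnds_ml(aln.seqs[0], aln.seqs[1])
            ng = ng86_dnds(aln.seqs[0], aln.seqs[1])
            assert ml.dn == pytest.approx(ng.dn, rel=0.20)
            assert ml.ds == pytest.approx(ng.ds, rel=0.20)

    def test_gapped_columns_dropped(self):
        x, y = gap_free_codon_columns("ATG---AAA", "ATGCCCAAA")
        assert len(x) == 2


class TestBranchAsymmetry:
    def test_nesting_holds(self):
        aln = simulate_codon_triplet(TripletTree(0.2, 0.2, 0.5), 2.0,
                                     [(1.0, (0.3,) * 3)], n_codons=300, seed=4)
        for which in ("omega", "dn"):
            r = branch_asymmetry_test(aln, which)
            assert r.ln_alt >= r.ln_null - 1e-6
            assert r.two_delta_l >= 0.0

    def test_detects_omega_asymmetry(self):
        aln = simulate_codon_triplet(TripletTree(0.2, 0.2, 0.5), 2.0,
                                     [(1.0, (1.0, 0.1, 0.3))],
                                     n_codons=1000, seed=2)
        r = branch_asymmetry_test(aln, "omega")
        assert r.p_value < 0.01

    def test_symmetric_data_not_rejected(self):
        aln = simulate_codon_triplet(TripletTree(0.2, 0.2, 0.5), 2.0,
                                     [(1.0, (0.3,) * 3)], n_codons=800, seed=3)
        r = branch_asymmetry_test(aln, "omega")
        assert r.p_value > 0.05

    def test_unknown_mode_rejected(self):
        aln = simulate_codon_triplet(TripletTree(0.1, 0.1, 0.1), 2.0,
                                     [(1.0, (0.3,) * 3)], n_codons=50, seed=1)
        with pytest.raises(ValueError):
            branch_asymmetry_test(aln, "ds")
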