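"""Behaviour of the sequence and cohort simulators."""

import numpy as np
import pytest
from scipy.linalg import expm

from dupreloc.codonmodels import CODON_AA, CODON_INDEX
from dupreloc.simulate import (
    CohortSpec,
    TripletTree,
    simulate_aa_triplet,
    simulate_codon_triplet,
    simulate_cohort,
)
from dupreloc.stats import build_contingency


class TestTripletTree:
    def test_rejects_negative_or_nonfinite(self):
        with pytest.raises(ValueError):
            TripletTree(-0.1, 0.1, 0.1)
        with pytest.raises(ValueError):
            TripletTree(np.inf, 0.1, 0.1)


class TestAminoAcidTriplets:
    def test_zero_branch_lengths_force_identity(self, jtt):
        aln = simulate_aa_triplet(TripletTree(0, 0, 0), jtt, 80, seed=1)
        assert len(set(aln.seqs)) == 1

    def test_same_seed_is_byte_identical(self, jtt):
        a = simulate_aa_triplet(TripletTree(0.1, 0.2, 0.3), jtt, 200, seed=42)
        b = simulate_aa_triplet(TripletTree(0.1, 0.2, 0.3), jtt, 200, seed=42)
        assert a.seqs == b.seqs

    def test_pairwise_difference_matches_closed_form(self, jtt):
        """The d1-d2 mismatch fraction at joint distance 0.2 should match
        1 - sum_i pi_i P(0.2)[i, i] computed by an independent matrix
        exponential, within 3 binomial standard errors."""
        n = 10_000
        aln = simulate_aa_triplet(TripletTree(0.1, 0.1, 0.2), jtt, n, seed=5)
        observed = np.mean([a != b for a, b in zip(aln.seqs[0], aln.seqs[1])])
        p = expm(jtt.rate_matrix * 0.2)
        expected = 1.0 - float(jtt.freqs @ np.diag(p))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    def test_n_sites_must_be_positive(self, jtt):
        with pytest.raises(ValueError):
            simulate_aa_triplet(TripletTree(0.1, 0.1, 0.1), jtt, 0)


class TestCodonTriplets:
    def test_omega_zero_means_only_synonymous_differences(self):
        tree = TripletTree(0.3, 0.3, 0.3)
        aln = simulate_codon_triplet(tree, 2.0, [(1.0, (0.0, 0.0, 0.0))],
                                     n_codons=400, seed=3)
        for seq in aln.seqs[1:]:
            for k in range(0, len(seq), 3):
                a, b = aln.seqs[0][k:k + 3], seq[k:k + 3]
                assert CODON_AA[CODON_INDEX[a]] == CODON_AA[CODON_INDEX[b]]

    def test_no_stop_codons(self):
        aln = simulate_codon_triplet(TripletTree(0.5, 0.5, 0.5), 2.0,
                                     [(1.0, (1.0, 1.0, 1.0))],
                                     n_codons=300, seed=4)
        for seq in aln.seqs:
            for k in range(0, len(seq), 3):
                assert seq[k:k + 3] in CODON_INDEX

    def test_same_seed_identical(self):
        kw = dict(kappa=2.0, site_classes=[(0.5, (0.1,) * 3), (0.5, (1.0,) * 3)],
                  n_codons=100, seed=9)
        a = simulate_codon_triplet(TripletTree(0.1, 0.2, 0.3), **kw)
        b = simulate_codon_triplet(TripletTree(0.1, 0.2, 0.3), **kw)
        assert a.seqs == b.seqs
        assert np.array_equal(a.site_classes, b.site_classes)

    def test_unnormalized_proportions_rejected(self):
        with pytest.raises(ValueError):
            simulate_codon_triplet(TripletTree(0.1, 0.1, 0.1), 2.0,
                                   [(0.6, (0.1,) * 3), (0.6, (1.0,) * 3)],
                                   n_codons=10)


class TestCohorts:
    def test_deterministic_counts_reproduce_study_table(self):
        spec = CohortSpec(128, 19, 8 / 19, 13 / 109, deterministic_counts=True)
        roster = simulate_cohort(spec)
        calls = ["complete_change" if r else "same" for r in roster["reloc_flag"]]
        table = build_contingency(calls, list(roster["asym_flag"]))
        assert table.tolist() == [[8, 11], [13, 96]]

    def test_same_seed_identical_roster(self):
        spec = CohortSpec(40, 10, 0.4, 0.1, seed=3)
        assert simulate_cohort(spec).equals(simulate_cohort(spec))

    def test_order_independent_substreams(self):
        """Pair i's flags depend on (seed, i) only, not on cohort size."""
        small = simulate_cohort(CohortSpec(20, 5, 0.5, 0.2, seed=8))
        large = simulate_cohort(CohortSpec(40, 5, 0.5, 0.2, seed=8))
        assert list(small["asym_flag"]) == list(large["asym_flag"][:20])

    def test_marginals_match_spec_probabilities(self):
        """Bernoulli mode: group asymmetry frequencies over many replicates
        stay within 3 standard errors of the requested probabilities."""
        p_r, p_s = 0.4, 0.12
        n_rep, n_pairs, n_reloc = 400, 64, 16
        a = c = 0
        for rep in range(n_rep):
            roster = simulate_cohort(CohortSpec(n_pairs, n_reloc, p_r, p_s, seed=rep))
            a += roster["asym_flag"][:n_reloc].sum()
            c += roster["asym_flag"][n_reloc:].sum()
        n_a, n_c = n_rep * n_reloc, n_rep * (n_pairs - n_reloc)
        assert abs(a / n_a - p_r) < 3 * np.sqrt(p_r * (1 - p_r) / n_a)
        assert abs(c / n_c - p_s) < 3 * np.sqrt(p_s * (1 - p_s) / n_c)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(10, 11, 0.5, 0.5)
        with pytest.raises(ValueError):
            CohortSpec(10, 5, 1.5, 0.5)


class TestCohortSpecFile:
    def test_round_trip_from_json(self, tmp_path):
        import json

        path = tmp_path / "spec.json"
        path.write_text(json.dumps({"n_pairs": 40, "n_relocalized": 8,
                                    "p_asym_reloc": 0.5, "seed": 3}))
        spec = CohortSpec.from_json(path)
        assert spec.n_pairs == 40 and spec.n_relocalized == 8
        assert spec.p_asym_same == 13 / 109  # default retained

    def test_unknown_key_rejected(self, tmp_path):
        import json

        path = tmp_path / "spec.json"
        path.write_text(json.dumps({"n_pair": 40}))
        with pytest.raises(ValueError, match="n_pair"):
            CohortSpec.from_json(path)
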