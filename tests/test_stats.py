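"""Localization classification, enrichment statistics, isoelectric points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dupreloc.stats import (
    EMBOSS_PK,
    build_contingency,
    classify_localization_pair,
    classify_table,
    delta_pi_ttest,
    dif_randomization,
    fisher_one_tailed,
    isoelectric_point,
    load_relocalized_pairs,
)



_TOKENS = ["cp", "mt", "cy", "cyb", "nu", "per", "pm", "er", "va"]
_SETS = st.sets(st.sampled_from(_TOKENS), min_size=1, max_size=4)

class TestClassification:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(a=_SETS, b=_SETS)
    def test_symmetric_for_any_sets(self, a, b):
        assert classify_localization_pair(a, b) == classify_localization_pair(b, a)

    @pytest.mark.parametrize("a,b,expected", [
        ({"cw"}, {"cy"}, "complete_change"),
        ({"mt", "cp"}, {"mt"}, "partial_change"),
        ({"nu"}, {"nu"}, "same"),
        ({"pm"}, {"Va"}, "complete_change"),   # case-insensitive tokens
        ({"nu", "cy"}, {"mt", "cy"}, "partial_change"),
    ])
    def test_examples(self, a, b, expected):
        assert classify_localization_pair(a, b) == expected

    def test_symmetric(self, rng):
        tokens = ["cp", "mt", "cy", "nu", "per", "pm", "er"]
        for _ in range(50):
            a = set(rng.choice(tokens, size=rng.integers(1, 4), replace=False))
            b = set(rng.choice(tokens, size=rng.integers(1, 4), replace=False))
            assert classify_localization_pair(a, b) == \
                classify_localization_pair(b, a)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            classify_localization_pair(set(), {"cy"})

    def test_relocalized_cohort_splits_fourteen_five(self):
        """The 19 relocalized pairs yield exactly 14 complete changes and
        5 expansion/contraction cases."""
        calls = classify_table(load_relocalized_pairs())["call"]
        assert (calls == "complete_change").sum() == 14
        assert (calls == "partial_change").sum() == 5


class TestContingency:
    def test_study_cohort_counts(self):
        calls = (["complete_change"] * 14 + ["partial_change"] * 5
                 + ["same"] * 109)
        asym = [True] * 8 + [False] * 11 + [True] * 13 + [False] * 96
        table = build_contingency(calls, asym)
        assert table.tolist() == [[8, 11], [13, 96]]

    def test_all_same_localized(self):
        table = build_contingency(["same", "same"], [True, False])
        assert table[0].sum() == 0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_contingency([], [])


def _fisher_enumeration(table):
    """Brute-force upper-tail hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n1, k = a + b, a + c
    total = a + b + c + d
    norm = 0.0
    tail = 0.0
    from math import comb

    for aa in range(max(0, k - (total - n1)), min(n1, k) + 1):
        p = comb(n1, aa) * comb(total - n1, k - aa)
        norm += p
        if aa >= a:
            tail += p
    return tail / norm


class TestFisher:
    def test_study_table(self):
        p = fisher_one_tailed([[8, 11], [13, 96]])
        assert p == pytest.approx(0.0034054, abs=1e-6)

    def test_zero_margin_gives_one(self):
        assert fisher_one_tailed([[0, 0], [3, 7]]) == 1.0

    def test_matches_enumeration_on_small_tables(self, rng):
        for _ in range(60):
            cells = rng.integers(0, 8, size=4)
            if cells.sum() == 0 or cells.sum() > 30:
                continue
            table = cells.reshape(2, 2)
            assert fisher_one_tailed(table) == \
                pytest.approx(_fisher_enumeration(table), abs=1e-12)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_tailed([[1.5, 2], [3, 4]])


class TestDifRandomization:
    def test_observed_statistic(self):
        r = dif_randomization((19, 109), (8, 13), n_sim=100, seed=1)
        assert r.dif_obs == pytest.approx(abs(8 / 19 - 13 / 109), abs=1e-12)
        assert r.dif_obs == pytest.approx(0.302, abs=5e-4)

    def test_equal_frequencies_give_p_one(self):
        r = dif_randomization((20, 100), (4, 20), n_sim=500, seed=2)
        assert r.dif_obs == 0.0
        assert r.mc_p == 1.0

    def test_seeded_reproducibility(self):
        a = dif_randomization((19, 109), (8, 13), n_sim=2000, seed=7)
        b = dif_randomization((19, 109), (8, 13), n_sim=2000, seed=7)
        assert a.mc_p == b.mc_p

    def test_schemes_agree_in_order_of_magnitude(self):
        res = dif_randomization((19, 109), (8, 13), n_sim=20_000, seed=3)
        perm = dif_randomization((19, 109), (8, 13), n_sim=20_000, seed=3,
                                 scheme="permute")
        assert 1e-4 < res.mc_p < 1e-2
        assert 1e-4 < perm.mc_p < 1e-2

    def test_null_calibration_under_resampling(self):
        """With no group difference the Monte Carlo p-value should be
        significant at 0.05 in roughly 5% of null cohorts."""
        rng = np.random.default_rng(0)
        n_rep, hits = 200, 0
        for rep in range(n_rep):
            flags_r = rng.random(19) < 0.16
            flags_s = rng.random(109) < 0.16
            r = dif_randomization((19, 109), (int(flags_r.sum()), int(flags_s.sum())),
                                  n_sim=400, seed=rep)
            if r.mc_p < 0.05:
                hits += 1
        assert hits / n_rep < 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_rep) + 0.025

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            dif_randomization((10, 10), (11, 0), n_sim=10)


class TestIsoelectricPoint:
    def test_glycine_dipeptide_midpoint(self):
        """With only the two termini titrating, the pI is the midpoint of
        their pK values: (8.6 + 3.6) / 2 = 6.10."""
        assert isoelectric_point("GG") == pytest.approx(6.10, abs=1e-3)

    def test_appending_lysine_raises_pi(self, rng):
        for seq in ("GG", "MKVAW", "DDEE"):
            assert isoelectric_point(seq + "K") > isoelectric_point(seq)

    def test_acidic_peptide_below_seven(self):
        assert isoelectric_point("D" * 10) < 7.0

    def test_matches_fine_grid_scan(self, rng):
        """Bisection agrees with an exhaustive 1e-5-step grid scan of the
        net-charge zero crossing."""
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        grid = np.arange(0.0, 14.0, 1e-5)
        for _ in range(100):
            seq = "".join(rng.choice(aas, size=rng.integers(5, 60)))
            basic = [("Nterm", 1), ("H", seq.count("H")),
                     ("K", seq.count("K")), ("R", seq.count("R"))]
            acidic = [("Cterm", 1), ("C", seq.count("C")), ("D", seq.count("D")),
                      ("E", seq.count("E")), ("Y", seq.count("Y"))]
            charges = (
                sum(n / (1 + 10 ** (grid - EMBOSS_PK[g])) for g, n in basic)
                - sum(n / (1 + 10 ** (EMBOSS_PK[g] - grid)) for g, n in acidic)
            )
            crossing = grid[np.argmin(np.abs(charges))]
            assert isoelectric_point(seq) == pytest.approx(crossing, abs=1e-3)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            isoelectric_point("")


class TestDeltaPiTtest:
    def test_identical_groups_give_p_one(self):
        res = delta_pi_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_welch(self):
        x, y = [1.0, 1.2, 0.8], [2.0, 2.2, 1.8]
        res = delta_pi_ttest(x, y)
        sx2 = np.var(x, ddof=1) / 3
        sy2 = np.var(y, ddof=1) / 3
        t_hand = (np.mean(x) - np.mean(y)) / np.sqrt(sx2 + sy2)
        df_hand = (sx2 + sy2) ** 2 / (sx2 ** 2 / 2 + sy2 ** 2 / 2)
        p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-12)
        assert res.df == pytest.approx(df_hand, abs=1e-9)
        assert res.p_value == pytest.approx(p_hand, abs=1e-12)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            delta_pi_ttest([1.0], [1.0, 2.0])
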