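"""Asymmetry screen: exact binomial statistics and parsimony assignment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import binom

from conftest import matrix_from_ds
from dupevol.asymmetry import (BestPair, SubstitutionAssignment,
                               assign_substitutions,
                               bidirectional_best_pairs, binom_symmetry_test,
                               meta_test, run_asymmetry_screen)
from dupevol.pipeline import load_fixture_table1
from dupevol.rates import rate_matrix
from dupevol.simulate import duplication_scenario


def exact_two_sided(x1: int, x2: int) -> float:
    """Independent oracle: exact rational tail of Binomial(n, 1/2)."""
    n = x1 + x2
    if n == 0:
        return 1.0
    k = min(x1, x2)
    tail = Fraction(sum(comb(n, i) for i in range(k + 1)), 2 ** n)
    return float(min(Fraction(1), 2 * tail))


class TestBinomSymmetryTest:
    def test_balanced_counts_give_one(self):
        for x in (0, 1, 7, 40):
            assert binom_symmetry_test(x, x) == 1.0

    def test_29_vs_1_exact_value(self):
        # 2 * (C(30,29) + C(30,30)) / 2^30 = 62 / 2^30
        assert binom_symmetry_test(29, 1) == pytest.approx(62 / 2 ** 30, rel=1e-12)

    def test_published_top_pair_significant(self):
        assert binom_symmetry_test(52, 8) < 0.05

    @pytest.mark.parametrize("x1,x2", [(0, 0), (3, 9), (12, 5), (52, 8),
                                       (29, 1), (100, 80)])
    def test_matches_exact_rational_oracle(self, x1, x2):
        assert binom_symmetry_test(x1, x2) == pytest.approx(
            exact_two_sided(x1, x2), rel=1e-12)
        assert binom_symmetry_test(x1, x2) == binom_symmetry_test(x2, x1)

    def test_monotone_in_imbalance(self):
        n = 40
        ps = [binom_symmetry_test(k, n - k) for k in range(n // 2, n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_one_sided_is_half_of_two_sided_off_center(self):
        assert binom_symmetry_test(30, 10, sided="one") == pytest.approx(
            binom_symmetry_test(30, 10) / 2, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            binom_symmetry_test(-1, 3)


class TestMetaTest:
    def test_zero_successes_gives_one(self):
        assert meta_test(0, 144) == 1.0

    def test_published_values(self):
        assert meta_test(26, 144, 0.05) == pytest.approx(1.33e-8, rel=5e-3)
        assert meta_test(9, 144, 0.05) == pytest.approx(0.295, rel=5e-3)

    @pytest.mark.parametrize("k,n,p", [(26, 144, 0.05), (9, 144, 0.05),
                                       (1, 10, 0.3), (500, 10000, 0.05),
                                       (9990, 10000, 0.99)])
    def test_agrees_with_scipy_sf_to_ten_digits(self, k, n, p):
        assert meta_test(k, n, p) == pytest.approx(
            float(binom.sf(k - 1, n, p)), rel=1e-10)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            meta_test(3, 2)
        with pytest.raises(ValueError):
            meta_test(1, 10, p_asym=0.0)
        with pytest.raises(ValueError):
            meta_test(1, 10, p_asym=1.0)


class TestAssignSubstitutions:
    # codons: M=ATG K=AAA R=AGA S=AGC V=GTT
    def test_outgroup_resolves_direction(self):
        a, b, c = "ATGAAAGTT", "ATGAGAGTT", "ATGAGAGTT"   # MKV / MRV / MRV
        res = assign_substitutions(a, b, c, channel="aa")
        assert (res.x1, res.x2) == (1, 0)
        assert res.excluded_all_differ == 0

    def test_all_three_differ_excluded(self):
        a, b, c = "ATGAAAGTT", "ATGAGAGTT", "ATGAGCGTT"   # MKV / MRV / MSV
        res = assign_substitutions(a, b, c, channel="aa")
        assert (res.x1, res.x2) == (0, 0)
        assert res.excluded_all_differ == 1

    def test_gap_columns_excluded_separately(self):
        a, b, c = "ATG---GTT", "ATGAGAGTT", "ATGAGAGTT"
        res = assign_substitutions(a, b, c, channel="aa")
        assert res.excluded_gap == 1
        assert (res.x1, res.x2) == (0, 0)

    def test_synonymous_channel_counts_silent_changes_only(self):
        # codon 2: CTT/CTC/CTC all Leu -> synonymous change in a (x1)
        # codon 3: AAA/AGA/AGA Lys vs Arg -> aa not conserved, not counted
        a = "ATG" + "CTT" + "AAA"
        b = "ATG" + "CTC" + "AGA"
        c = "ATG" + "CTC" + "AGA"
        res = assign_substitutions(a, b, c, channel="syn")
        assert (res.x1, res.x2) == (1, 0)
        aa = assign_substitutions(a, b, c, channel="aa")
        assert (aa.x1, aa.x2) == (1, 0)   # the Lys->Arg change goes to a

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_substitutions("ATG", "ATGGTT", "ATG")

    def test_negative_assignment_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionAssignment(-1, 0, 0, 0, "aa")


class TestBestPairs:
    def test_simple_family(self):
        m = matrix_from_ds({("i", "j"): 0.1, ("i", "k"): 0.5,
                            ("j", "k"): 0.6})
        pairs = bidirectional_best_pairs(m)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.gene_a, p.gene_b, p.cousin_c) == ("i", "j", "k")

    def test_non_mutual_sisters_unpaired(self):
        # a's sister is b, but b's sister is c
        m = matrix_from_ds({("a", "b"): 0.3, ("b", "c"): 0.1,
                            ("a", "c"): 0.5, ("a", "d"): 0.9,
                            ("b", "d"): 0.9, ("c", "d"): 0.9})
        pairs = bidirectional_best_pairs(m)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("b", "c")]

    def test_cousin_minimizes_ds_sum(self):
        m = matrix_from_ds({("i", "j"): 0.1, ("i", "k"): 0.5, ("j", "k"): 0.9,
                            ("i", "l"): 0.6, ("j", "l"): 0.6, ("k", "l"): 0.3})
        p = bidirectional_best_pairs(m)[0]
        assert p.cousin_c == "l"   # 1.2 < 1.4

    def test_cousin_tie_breaks_lexicographically(self):
        m = matrix_from_ds({("i", "j"): 0.1, ("i", "k"): 0.5, ("j", "k"): 0.6,
                            ("i", "l"): 0.5, ("j", "l"): 0.6, ("k", "l"): 0.3})
        assert bidirectional_best_pairs(m)[0].cousin_c == "k"

    def test_invalid_cousin_drops_pair(self):
        # i/j mutual sisters (ties break toward smaller id), but k is
        # exactly as close as the pair distance, violating the strict
        # outgroup inequalities
        m = matrix_from_ds({("i", "j"): 0.3, ("i", "k"): 0.3, ("j", "k"): 0.3})
        assert bidirectional_best_pairs(m) == []

    def test_outgroup_inequalities_enforced_in_type(self):
        with pytest.raises(ValueError):
            BestPair("f", "a", "b", "c", dS_ab=0.5, dS_ac=0.4, dS_bc=0.6)


class TestScreen:
    def test_accelerated_copy_accumulates_more(self):
        x1s, x2s = [], []
        for seed in range(40):
            truth = duplication_scenario(0.05, 0.5, omega=0.3,
                                         accel_factor=5.0, n_codons=800,
                                         seed=seed)
            aln = truth.alignment
            res = assign_substitutions(aln["i"], aln["j"], aln["k"], "aa")
            x1s.append(res.x1)
            x2s.append(res.x2)
        assert np.mean(x1s) > 2 * np.mean(x2s)

    def test_identical_family_yields_no_pairs(self):
        aln = {g: "ATGGCTAAAGTTCCAGAT" * 10 for g in "abc"}
        m = rate_matrix(aln, "fam")
        results, meta = run_asymmetry_screen([m], {"fam": aln})
        assert results == [] and meta.n_pairs == 0 and meta.p_value == 1.0

    def test_table1_counts_all_significant(self):
        rows = load_fixture_table1()
        ps = [binom_symmetry_test(x_fast, x_slow)
              for _, _, x_fast, x_slow in rows]
        assert len(ps) == 26
        assert all(p < 0.05 for p in ps)
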