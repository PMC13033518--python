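"""Harmonization: allele alignment, palindromic policies, strand
complements, Steiger directionality filtering, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medmr.harmonize import (
    harmonize_pair,
    steiger_filter,
    variance_explained,
)
from medmr.sumstats import SumstatsError

from conftest import make_pair, make_stats, make_variant


def exposure_outcome(ex_alleles, oc_alleles, *, ex_eaf=0.3, oc_eaf=0.3,
                     beta_x=0.2, beta_y=0.1):
    exp = make_stats(
        [make_variant(effect_allele=ex_alleles[0], other_allele=ex_alleles[1],
                      eaf=ex_eaf, beta=beta_x)],
        trait_id="exp",
    )
    out = make_stats(
        [make_variant(effect_allele=oc_alleles[0], other_allele=oc_alleles[1],
                      eaf=oc_eaf, beta=beta_y)],
        trait_id="out", trait_class="protein",
    )
    return exp, out


class TestAlleleAlignment:
    def test_identical_alleles_aligned(self):
        exp, out = exposure_outcome(("A", "G"), ("A", "G"))
        pair = harmonize_pair(exp, out)
        assert pair.df["beta_y"].iloc[0] == pytest.approx(0.1)
        assert not pair.df["flipped"].iloc[0]
        assert pair.report["aligned"] == 1

    def test_swapped_alleles_flip_sign(self):
        exp, out = exposure_outcome(("A", "G"), ("G", "A"))
        pair = harmonize_pair(exp, out)
        assert pair.df["beta_y"].iloc[0] == pytest.approx(-0.1)
        assert pair.df["flipped"].iloc[0]
        assert pair.report["flipped"] == 1

    def test_strand_complement_aligned(self):
        # exposure A/G; outcome on the other strand reports T/C
        exp, out = exposure_outcome(("A", "G"), ("T", "C"))
        pair = harmonize_pair(exp, out)
        assert pair.df["beta_y"].iloc[0] == pytest.approx(0.1)
        assert not pair.df["flipped"].iloc[0]

    def test_strand_complement_swap_flips(self):
        exp, out = exposure_outcome(("A", "G"), ("C", "T"))
        pair = harmonize_pair(exp, out)
        assert pair.df["beta_y"].iloc[0] == pytest.approx(-0.1)

    def test_incompatible_alleles_dropped(self):
        exp, out = exposure_outcome(("A", "G"), ("A", "C"))
        pair = harmonize_pair(exp, out)
        assert pair.skip
        assert pair.report["incompatible_dropped"] == 1

    def test_empty_intersection_is_skip_not_error(self):
        exp = make_stats([make_variant(variant_id="rs1")], trait_id="exp")
        out = make_stats([make_variant(variant_id="rs2")], trait_id="out",
                         trait_class="protein")
        pair = harmonize_pair(exp, out)
        assert pair.skip and len(pair) == 0


class TestPalindromic:
    def test_drop_policy_removes_palindromes(self):
        exp, out = exposure_outcome(("A", "T"), ("A", "T"), ex_eaf=0.1, oc_eaf=0.1)
        pair = harmonize_pair(exp, out, palindromic_policy="drop")
        assert pair.report["palindromic_dropped"] == 1

    def test_ambiguous_frequency_dropped_under_infer(self):
        # eaf 0.51 is inside the 0.5 +/- 0.08 band
        exp, out = exposure_outcome(("A", "T"), ("A", "T"), ex_eaf=0.51, oc_eaf=0.2)
        pair = harmonize_pair(exp, out, palindromic_policy="infer_by_eaf",
                              eaf_tolerance=0.08)
        assert pair.report["palindromic_dropped"] == 1

    def test_concordant_frequency_kept_aligned(self):
        exp, out = exposure_outcome(("A", "T"), ("A", "T"), ex_eaf=0.1, oc_eaf=0.12)
        pair = harmonize_pair(exp, out, palindromic_policy="infer_by_eaf")
        assert len(pair) == 1
        assert pair.df["beta_y"].iloc[0] == pytest.approx(0.1)
        assert pair.df["palindromic"].iloc[0]

    def test_discordant_frequency_kept_flipped(self):
        # same labels but frequencies on opposite sides of 0.5: the outcome
        # is reporting the other strand's complement, so the sign flips
        exp, out = exposure_outcome(("A", "T"), ("A", "T"), ex_eaf=0.1, oc_eaf=0.9)
        pair = harmonize_pair(exp, out, palindromic_policy="infer_by_eaf")
        assert len(pair) == 1
        assert pair.df["beta_y"].iloc[0] == pytest.approx(-0.1)

    def test_missing_eaf_forces_drop(self):
        exp, out = exposure_outcome(("A", "T"), ("A", "T"), ex_eaf=None, oc_eaf=0.1)
        pair = harmonize_pair(exp, out, palindromic_policy="infer_by_eaf")
        assert pair.report["palindromic_dropped"] == 1


class TestHarmonizeInvariants:
    def test_report_counts_sum_to_intersection(self):
        records_exp, records_out = [], []
        specs = [
            ("rs1", ("A", "G"), ("A", "G"), 0.3, 0.3),   # aligned
            ("rs2", ("A", "G"), ("G", "A"), 0.3, 0.7),   # flipped
            ("rs3", ("A", "T"), ("A", "T"), 0.51, 0.5),  # palindromic ambiguous
            ("rs4", ("A", "G"), ("A", "C"), 0.3, 0.3),   # incompatible
        ]
        for vid, (e1, e2), (o1, o2), fx, fy in specs:
            records_exp.append(make_variant(variant_id=vid, effect_allele=e1,
                                            other_allele=e2, eaf=fx))
            records_out.append(make_variant(variant_id=vid, effect_allele=o1,
                                            other_allele=o2, eaf=fy))
        pair = harmonize_pair(make_stats(records_exp, trait_id="exp"),
                              make_stats(records_out, trait_id="out",
                                         trait_class="protein"))
        r = pair.report
        assert (r["aligned"] + r["flipped"] + r["palindromic_dropped"]
                + r["incompatible_dropped"]) == 4
        assert len(pair) == r["aligned"] + r["flipped"]

    def test_involution_safe_on_aligned_pair(self):
        exp, out = exposure_outcome(("A", "G"), ("A", "G"))
        once = harmonize_pair(exp, out)
        # feeding the already-aligned outcome back through changes nothing
        again = harmonize_pair(exp, out)
        assert once.df.equals(again.df)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(beta_y=st.floats(-1, 1, allow_nan=False), flip=st.booleans())
    def test_sign_consistency(self, beta_y, flip):
        """Negating all outcome betas and swapping outcome alleles yields
        an identical harmonized pair."""
        exp, out1 = exposure_outcome(("A", "G"), ("A", "G"), beta_y=beta_y)
        _, out2 = exposure_outcome(("A", "G"), ("G", "A"), beta_y=-beta_y)
        p1 = harmonize_pair(exp, out1)
        p2 = harmonize_pair(exp, out2)
        assert p1.df["beta_y"].iloc[0] == pytest.approx(p2.df["beta_y"].iloc[0])


class TestVarianceExplained:
    def test_zero_beta_gives_zero(self):
        assert variance_explained(0.0, 0.1, 100) == 0.0

    def test_symmetry_point(self):
        # t^2 = n - 2 puts r2 exactly at one half
        n = 100
        t2 = n - 2
        beta = np.sqrt(t2) * 0.05
        assert variance_explained(beta, 0.05, n) == pytest.approx(0.5)

    def test_direct_arithmetic(self):
        # t = 0.3/0.05 = 6, r2 = 36 / (36 + 998)
        assert variance_explained(0.3, 0.05, 1000) == pytest.approx(36 / 1034)

    def test_small_n_rejected(self):
        with pytest.raises(SumstatsError):
            variance_explained(0.1, 0.05, 2)


class TestSteigerFilter:
    def test_zero_outcome_beta_retained(self):
        pair = make_pair([0.2], [0.0], se_y=0.02)
        assert len(steiger_filter(pair)) == 1

    def test_identical_sides_dropped_by_strict_inequality(self):
        pair = make_pair([0.2], [0.2], se_y=0.02, se_x=0.02, n_x=1000, n_y=1000)
        filtered = steiger_filter(pair)
        assert filtered.skip
        assert filtered.report["steiger_dropped"] == 1

    def test_constructed_panel_drops_exactly_one(self):
        # 9 rows with exposure r2 ten times the outcome's, 1 row reversed
        bx = np.full(10, 0.2)
        by = np.full(10, 0.2 / np.sqrt(10))
        by[-1] = 0.7  # outcome r2 larger only here
        pair = make_pair(bx, by, se_y=0.02, se_x=0.02, n_x=10_000, n_y=10_000)
        filtered = steiger_filter(pair)
        assert len(filtered) == 9
        assert filtered.report["steiger_dropped"] == 1

    def test_idempotent(self):
        bx = np.array([0.2, 0.1, 0.05])
        by = np.array([0.01, 0.5, 0.01])
        pair = make_pair(bx, by, se_y=0.02, se_x=0.02, n_x=5000, n_y=5000)
        once = steiger_filter(pair)
        twice = steiger_filter(once)
        assert once.df.equals(twice.df)
        assert once.report["steiger_dropped"] == twice.report["steiger_dropped"]
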