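import math

import numpy as np
import pytest

from fisherseq.counting import ClassCounts, EventCounts
from fisherseq.splicing import (
    RETAINED_INTRON,
    SKIPPED_EXON,
    differential_splicing,
    retained_intron_test,
    skipped_exon_test,
    splice_direction,
)

from conftest import assert_close, fisher_enum


class TestSkippedExonTest:
    def test_equal_ratios_p1(self):
        assert skipped_exon_test(10, 5, 5, 20, 10, 10) == pytest.approx(1.0)

    def test_frozen_enumeration_value(self):
        # oracle-computed: [[8, 2], [2, 8]]
        assert skipped_exon_test(8, 2, 0, 2, 8, 0) == pytest.approx(
            0.02301413756522116, rel=1e-9)

    def test_zero_inclusion_both_p1(self):
        assert skipped_exon_test(0, 9, 1, 0, 5, 5) == pytest.approx(1.0)

    def test_all_zero_untestable(self):
        assert math.isnan(skipped_exon_test(0, 0, 0, 0, 0, 0))

    def test_flanking_pools_with_skipping(self):
        # flanking enters the denominator with weight 1, like skipping
        assert skipped_exon_test(5, 3, 4, 6, 0, 2) == pytest.approx(
            skipped_exon_test(5, 7, 0, 6, 2, 0))


class TestRetainedIntronTest:
    def test_equal_ratios_p1(self):
        assert retained_intron_test(10, 40, 20, 80) == pytest.approx(1.0)

    def test_frozen_enumeration_value(self):
        assert retained_intron_test(30, 10, 10, 30) == pytest.approx(
            1.4874803071085419e-05, rel=1e-9)

    def test_zero_inclusion_both_p1(self):
        assert retained_intron_test(0, 100, 0, 100) == pytest.approx(1.0)

    def test_all_zero_untestable(self):
        assert math.isnan(retained_intron_test(0, 0, 0, 0))

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 50, 4)
            if a + b + c + d == 0:
                continue
            assert_close(retained_intron_test(a, b, c, d),
                         fisher_enum(a, b, c, d), rel=1e-8)


class TestDirection:
    def test_inclusion_falls_increased_skipping(self):
        assert splice_direction(SKIPPED_EXON, ClassCounts(2, 10, 0),
                                ClassCounts(10, 2, 0)) == "increased_skipping"

    def test_symmetric_swap_decreased_skipping(self):
        assert splice_direction(SKIPPED_EXON, ClassCounts(10, 2, 0),
                                ClassCounts(2, 10, 0)) == "decreased_skipping"

    def test_retention_ratio_rises(self):
        assert splice_direction(
            RETAINED_INTRON,
            ClassCounts(20, 0, 50),
            ClassCounts(5, 0, 50)) == "increased_retention"

    def test_retention_ratio_falls(self):
        assert splice_direction(
            RETAINED_INTRON,
            ClassCounts(5, 0, 50),
            ClassCounts(20, 0, 50)) == "decreased_retention"

    def test_defined_at_zero_counts(self):
        # the continuity adjustment keeps the call defined for empty cells
        assert splice_direction(SKIPPED_EXON, ClassCounts(0, 0, 0),
                                ClassCounts(5, 0, 0)) == "increased_skipping"


def _event_counts(cond, se=None, ri=None):
    counts = {}
    if se is not None:
        counts["se1"] = ClassCounts(*se)
    if ri is not None:
        counts["ri1"] = ClassCounts(*ri)
    return EventCounts(cond, counts)


class TestDifferentialSplicing:
    types = {"se1": SKIPPED_EXON, "ri1": RETAINED_INTRON}

    def test_per_type_bonferroni(self):
        a = _event_counts("a", se=(10, 40, 10), ri=(30, 0, 10))
        b = _event_counts("b", se=(40, 10, 10), ri=(10, 0, 30))
        results = {r.event_id: r for r in
                   differential_splicing(a, b, self.types)}
        # one testable event per type, so m = 1 within each type
        for r in results.values():
            assert r.p_adj == pytest.approx(min(1.0, r.p_raw))

    def test_untestable_event_excluded(self):
        a = _event_counts("a", se=(0, 0, 0), ri=(30, 0, 10))
        b = _event_counts("b", se=(0, 0, 0), ri=(10, 0, 30))
        results = differential_splicing(a, b, self.types)
        assert [r.event_id for r in results] == ["ri1"]

    def test_delta_log2_continuity_adjusted(self):
        a = _event_counts("a", se=(10, 5, 5))
        b = _event_counts("b", se=(20, 10, 10))
        r = differential_splicing(a, b, self.types)[0]
        expected_a = (5 + 5 + 0.5) / (10 + 0.5)
        expected_b = (10 + 10 + 0.5) / (20 + 0.5)
        assert r.ratio_a == pytest.approx(expected_a)
        assert r.ratio_b == pytest.approx(expected_b)
        assert r.delta_log2 == pytest.approx(
            math.log2(expected_a / expected_b))


def test_p_decreases_with_inclusion_shift():
    """Monotonicity: expected P falls as the simulated inclusion difference
    grows at fixed depth."""
    rng = np.random.default_rng(5)
    depth, psi_ref = 200, 0.5
    mean_log10p = []
    for shift in (0.0, 0.5, 1.0, 2.0):
        psi = 1.0 / (1.0 + math.exp(-(0.0 + shift)))  # logit(0.5) + shift
        logps = []
        for _ in range(40):
            incl_a = rng.binomial(depth, psi)
            incl_b = rng.binomial(depth, psi_ref)
            p = skipped_exon_test(incl_a, depth - incl_a, 0,
                                  incl_b, depth - incl_b, 0)
            logps.append(math.log10(max(p, 1e-300)))
        mean_log10p.append(np.mean(logps))
    assert mean_log10p[0] > mean_log10p[1] > mean_log10p[2] > mean_log10p[3]


def test_direction_call_accuracy_under_strong_shifts():
    """Direction calls match the simulated truth for >= 2-fold ratio shifts
    at >= 50 reads per class."""
    rng = np.random.default_rng(6)
    correct = total = 0
    for _ in range(200):
        more_skipping = rng.random() < 0.5
        psi_ref = rng.uniform(0.35, 0.65)
        odds = psi_ref / (1 - psi_ref)
        odds_cond = odds / 2 if more_skipping else odds * 2
        psi_cond = odds_cond / (1 + odds_cond)
        n = 300  # keeps every class near or above 50 reads
        a = ClassCounts(int(rng.binomial(n, psi_cond)), 0, 0)
        a = ClassCounts(a.inclusion, n - a.inclusion, 0)
        b = ClassCounts(int(rng.binomial(n, psi_ref)), 0, 0)
        b = ClassCounts(b.inclusion, n - b.inclusion, 0)
        call = splice_direction(SKIPPED_EXON, a, b)
        truth = "increased_skipping" if more_skipping else "decreased_skipping"
        correct += call == truth
        total += 1
    assert correct / total >= 0.99
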