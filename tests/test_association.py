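"""Per-locus case-control association statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import hypergeom

from crabsnp.association import (
    ContingencyTable,
    carrier_contingency,
    chi2_2x2,
    chi2_pvalue_df1,
    fisher_exact_2x2,
    genotype_counts,
    logistic_from_table,
    logistic_single_locus,
    odds_ratio,
    woolf_ci,
)
from crabsnp.genotypes import Genotype

from conftest import make_table


def fisher_enumeration_oracle(n1, n2, n3, n4):
    """Two-sided Fisher p by full enumeration over the hypergeometric
    support: sum the probabilities of all tables (with the observed margins)
    no more probable than the observed one."""
    r1 = n1 + n2
    c1 = n1 + n3
    n = n1 + n2 + n3 + n4
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(n1, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())


class TestContingency:
    def test_counts_direct(self, two_group_table):
        t = carrier_contingency(two_group_table, two_group_table.loci[0])
        assert t.cells == (3, 7, 1, 9)

    def test_all_wild_type(self):
        gt = make_table([[Genotype.HOM_REF]] * 8, ["tolerant"] * 5 + ["intolerant"] * 3)
        t = carrier_contingency(gt, gt.loci[0])
        assert t.cells == (0, 5, 0, 3)

    def test_missing_excluded(self):
        rows = [[Genotype.HET], [Genotype.MISSING], [Genotype.HOM_REF], [Genotype.HOM_ALT]]
        gt = make_table(rows, ["tolerant", "tolerant", "intolerant", "intolerant"])
        t = carrier_contingency(gt, gt.loci[0])
        assert t.cells == (1, 0, 1, 1)

    def test_empty_group_is_error(self):
        gt = make_table([[Genotype.HET]] * 3, ["tolerant"] * 3)
        with pytest.raises(ValueError, match="intolerant"):
            carrier_contingency(gt, gt.loci[0])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    def test_genotype_counts_three_rows(self, two_group_table):
        df = genotype_counts(two_group_table, two_group_table.loci[0])
        assert df["tolerant"].tolist() == [7, 3, 0]
        assert df["intolerant"].tolist() == [9, 1, 0]


class TestOddsRatio:
    def test_printed_haplotype_row(self):
        # tolerant 13.00 carriers of 96.86 total vs intolerant 2 of 96
        assert odds_ratio(ContingencyTable(13.00, 83.86, 2.00, 94.00)) == pytest.approx(
            7.286, abs=0.01
        )

    def test_symmetric_table_is_one(self):
        assert odds_ratio(ContingencyTable(10, 10, 10, 10)) == 1.0

    def test_zero_cell_undefined(self):
        assert odds_ratio(ContingencyTable(15.41, 81.45, 0.00, 96.00)) is None

    @given(
        cells=st.tuples(*[st.integers(min_value=1, max_value=50)] * 4)
    )
    def test_group_swap_inverts(self, cells):
        t = ContingencyTable(*cells)
        assert odds_ratio(t) * odds_ratio(t.swapped_groups()) == pytest.approx(1.0)


class TestWoolfCi:
    def test_printed_interval(self):
        lo, hi = woolf_ci(ContingencyTable(13.00, 83.86, 2.00, 94.00))
        assert lo == pytest.approx(1.597, abs=0.05)
        assert hi == pytest.approx(33.234, abs=0.05)

    def test_symmetric_hand_value(self):
        # exp(+/- 1.96 * sqrt(4/10)) around OR = 1
        lo, hi = woolf_ci(ContingencyTable(10, 10, 10, 10))
        assert lo == pytest.approx(math.exp(-1.96 * math.sqrt(0.4)), abs=1e-3)
        assert hi == pytest.approx(math.exp(1.96 * math.sqrt(0.4)), abs=1e-3)

    def test_zero_cell_undefined(self):
        assert woolf_ci(ContingencyTable(0, 10, 10, 10)) is None

    def test_interval_brackets_or(self):
        t = ContingencyTable(30, 20, 10, 40)
        lo, hi = woolf_ci(t)
        assert lo <= odds_ratio(t) <= hi


class TestChi2:
    def test_printed_haplotype_row(self):
        assert chi2_2x2(ContingencyTable(45.53, 51.33, 93.00, 3.00)) == pytest.approx(
            59.251, abs=0.15
        )

    def test_proportional_rows_zero(self):
        assert chi2_2x2(ContingencyTable(10, 20, 5, 10)) == pytest.approx(0.0)

    def test_hand_value(self):
        assert chi2_2x2(ContingencyTable(10, 20, 20, 10)) == pytest.approx(6.6667, abs=1e-3)

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi2_2x2(ContingencyTable(0, 10, 0, 10))

    @given(cells=st.tuples(*[st.integers(min_value=1, max_value=30)] * 4))
    def test_invariant_under_row_and_column_swap(self, cells):
        n1, n2, n3, n4 = cells
        a = chi2_2x2(ContingencyTable(n1, n2, n3, n4))
        b = chi2_2x2(ContingencyTable(n4, n3, n2, n1))
        assert a == pytest.approx(b)


class TestChi2Pvalue:
    def test_printed_value(self):
        assert chi2_pvalue_df1(7.182) == pytest.approx(0.0074, abs=0.0002)

    def test_zero_statistic(self):
        assert chi2_pvalue_df1(0.0) == 1.0

    def test_critical_value_against_integration_oracle(self):
        # independent oracle: quadrature of the chi-square(1) density
        density = lambda x: math.exp(-x / 2.0) / math.sqrt(2.0 * math.pi * x)
        expected, _ = integrate.quad(density, 3.841, np.inf)
        assert expected == pytest.approx(0.0500, abs=0.0005)
        assert chi2_pvalue_df1(3.841) == pytest.approx(expected, abs=1e-8)


class TestFisherExact:
    def test_most_probable_table(self):
        assert fisher_exact_2x2(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_perfect_separation(self):
        # 2 / C(20,10) by direct combinatorics
        assert fisher_exact_2x2(ContingencyTable(0, 10, 10, 0)) == pytest.approx(
            2 / math.comb(20, 10), abs=1e-9
        )

    def test_enumerated_value(self):
        assert fisher_exact_2x2(ContingencyTable(3, 7, 7, 3)) == pytest.approx(
            fisher_enumeration_oracle(3, 7, 7, 3), abs=1e-5
        )
        assert fisher_exact_2x2(ContingencyTable(3, 7, 7, 3)) == pytest.approx(0.17889, abs=1e-5)

    def test_fractional_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fisher_exact_2x2(ContingencyTable(1.5, 2, 3, 4))

    def test_half_even_rounding(self):
        t = ContingencyTable(1.5, 2.5, 3.0, 4.0).rounded_half_even()
        assert t.cells == (2.0, 2.0, 3.0, 4.0)

    @given(cells=st.tuples(*[st.integers(min_value=0, max_value=10)] * 4))
    def test_matches_enumeration_oracle(self, cells):
        if sum(cells) == 0:
            return
        n1, n2, n3, n4 = cells
        if (n1 + n2) == 0 or (n3 + n4) == 0 or (n1 + n3) == 0 or (n2 + n4) == 0:
            return
        assert fisher_exact_2x2(ContingencyTable(*cells)) == pytest.approx(
            fisher_enumeration_oracle(*cells), abs=1e-9
        )


class TestLogistic:
    def test_slope_is_log_odds_ratio(self):
        res = logistic_from_table(ContingencyTable(30, 20, 10, 40))
        assert res.log_or == pytest.approx(math.log(6.0), abs=1e-6)

    def test_equal_proportions_zero_slope(self):
        res = logistic_from_table(ContingencyTable(10, 10, 10, 10))
        assert res.log_or == pytest.approx(0.0, abs=1e-8)
        assert res.se == pytest.approx(math.sqrt(0.4), abs=1e-6)

    def test_separation_flagged(self):
        res = logistic_from_table(ContingencyTable(10, 0, 5, 5))
        assert res.separation
        assert res.log_or is None

    def test_from_genotype_table(self, two_group_table):
        res = logistic_single_locus(two_group_table, two_group_table.loci[0])
        t = carrier_contingency(two_group_table, two_group_table.loci[0])
        assert res.log_or == pytest.approx(math.log(odds_ratio(t)), abs=1e-6)

    @given(cells=st.tuples(*[st.integers(min_value=1, max_value=40)] * 4))
    def test_irls_slope_equals_closed_form(self, cells):
        t = ContingencyTable(*cells)
        res = logistic_from_table(t)
        assert res.log_or == pytest.approx(math.log(odds_ratio(t)), abs=1e-6)
        assert res.se == pytest.approx(math.sqrt(sum(1 / c for c in cells)), abs=1e-6)
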