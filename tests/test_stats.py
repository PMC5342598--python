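import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from ncrsplice.assays import Receptor
from ncrsplice.classify import ProfileCall, ProfileLabel
from ncrsplice.errors import DegenerateVarianceError
from ncrsplice.stats import (
    ContingencyTable2x2,
    TestMethod as StatMethod,
    compare_groups,
    fisher_exact_two_sided,
    incidence,
    paired_t_two_tail,
    profile_distribution,
)


def exact_fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by rational-arithmetic enumeration (independent path)."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    if 0 in (row1, row2, col1, b + d):
        return 1.0
    denom = math.comb(n, col1)
    p_obs = Fraction(math.comb(row1, a) * math.comb(row2, c), denom)
    total = Fraction(0)
    for k in range(max(0, col1 - row2), min(col1, row1) + 1):
        p_k = Fraction(math.comb(row1, k) * math.comb(row2, col1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)


def _calls(n_by_label):
    out = []
    for label, n in n_by_label.items():
        out += [ProfileCall(f"s{label.value}{i}", Receptor.NKP44, label) for i in range(n)]
    return out


class TestIncidence:
    @pytest.mark.parametrize(
        "n_pos,n_neg,pct", [(21, 2, 91.3), (7, 0, 100.0), (0, 5, 0.0)]
    )
    def test_published_style_ratios(self, n_pos, n_neg, pct):
        calls = _calls(
            {ProfileLabel.NKP44_1_DOMINANT: n_pos, ProfileLabel.NEGATIVE: n_neg}
        )
        summary = incidence(calls, "g")
        assert summary.n_positive == n_pos and summary.n_total == n_pos + n_neg
        assert round(summary.percent_positive, 1) == pct

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            incidence([], "g")


class TestProfileDistribution:
    @pytest.mark.parametrize(
        "n_dom,n_other,pcts",
        [(6, 1, (85.71, 14.29)), (8, 7, (53.33, 46.67)), (4, 4, (50.0, 50.0))],
    )
    def test_percentages_over_positive_cases(self, n_dom, n_other, pcts):
        calls = _calls(
            {
                ProfileLabel.NKP44_1_DOMINANT: n_dom,
                ProfileLabel.NKP44_2_3: n_other,
                ProfileLabel.NEGATIVE: 3,
            }
        )
        dist = profile_distribution(calls, "g")
        assert dist.n_positive == n_dom + n_other
        assert round(dist.percents[ProfileLabel.NKP44_1_DOMINANT], 2) == pcts[0]
        assert round(dist.percents[ProfileLabel.NKP44_2_3], 2) == pcts[1]

    def test_counts_reconstruct_from_percents(self):
        dist = profile_distribution(
            _calls({ProfileLabel.NKP44_1_DOMINANT: 11, ProfileLabel.NKP44_2_3: 4}), "g"
        )
        for label, pct in dist.percents.items():
            assert round(pct * dist.n_positive / 100) == dist.counts[label]

    def test_all_negative_distinguished_from_empty(self):
        with pytest.raises(ValueError, match="no positive"):
            profile_distribution(_calls({ProfileLabel.NEGATIVE: 4}), "g")
        with pytest.raises(ValueError, match="empty"):
            profile_distribution([], "g")


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5)).p_value == 1.0

    def test_elective_vs_spontaneous_table(self):
        # support a in 0..7 with margins (7,21)x(11,17): p(6)+p(7) = (7854+330)/1184040
        res = fisher_exact_two_sided(ContingencyTable2x2(6, 1, 5, 16))
        assert res.p_value == pytest.approx((7854 + 330) / 1184040, rel=1e-9)
        assert res.p_value <= 0.05

    def test_extreme_diagonal_table(self):
        res = fisher_exact_two_sided(ContingencyTable2x2(10, 0, 0, 10))
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_zero_margin_convention(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 4)).p_value == 1.0
        assert fisher_exact_two_sided(ContingencyTable2x2(0, 5, 0, 4)).p_value == 1.0

    def test_point_probability_always_included(self):
        res = fisher_exact_two_sided(ContingencyTable2x2(3, 9, 8, 2))
        p_point = float(sps.hypergeom.pmf(3, 22, 12, 11))
        assert res.p_value >= p_point > 0

    @given(
        a=st.integers(0, 15),
        b=st.integers(0, 15),
        c=st.integers(0, 15),
        d=st.integers(0, 15),
    )
    def test_invariant_under_row_and_column_swap(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d)).p_value
        p_swapped = fisher_exact_two_sided(ContingencyTable2x2(d, c, b, a)).p_value
        assert p == pytest.approx(p_swapped, rel=1e-12)

    def test_matches_rational_oracle_on_random_tables(self):
        rng = np.random.default_rng(2016)
        for _ in range(400):
            a, b, c, d = rng.integers(0, 16, size=4)
            if a + b + c + d == 0:
                continue
            got = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d)).p_value
            want = exact_fisher_oracle(int(a), int(b), int(c), int(d))
            assert got == pytest.approx(want, abs=1e-9)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            got = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d)).p_value
            want = float(sps.fisher_exact([[a, b], [c, d]])[1])
            assert got == pytest.approx(want, rel=1e-7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestPairedT:
    def test_df2_closed_form(self):
        # d = (1,2,3): t = 2*sqrt(3), p = 1 - t/sqrt(t^2+2) at df 2
        res = paired_t_two_tail([(1.0, 0.0), (2.0, 0.0), (3.0, 0.0)])
        assert res.statistic == pytest.approx(2 * math.sqrt(3), rel=1e-12)
        t = 2 * math.sqrt(3)
        assert res.p_value == pytest.approx(1 - t / math.sqrt(t * t + 2), rel=1e-9)
        assert round(res.p_value, 4) == 0.0742

    def test_zero_mean_differences(self):
        res = paired_t_two_tail([(2, 0), (-2, 0), (2, 0), (-2, 0)])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            paired_t_two_tail([(1, 0), (1, 0), (1, 0)])
        with pytest.raises(ValueError):
            paired_t_two_tail([(1, 0)])

    @given(
        diffs=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=3, max_size=12
        )
    )
    def test_antisymmetry(self, diffs):
        pairs = [(d, 0.0) for d in diffs]
        if len(set(diffs)) < 2:
            return
        fwd = paired_t_two_tail(pairs)
        rev = paired_t_two_tail([(y, x) for x, y in pairs])
        assert rev.statistic == pytest.approx(-fwd.statistic, rel=1e-9, abs=1e-12)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = paired_t_two_tail(list(zip(x, y)))
        t, p = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(float(t), rel=1e-12)
        assert res.p_value == pytest.approx(float(p), rel=1e-12)


class TestCompareGroups:
    def test_elective_vs_spontaneous_significant(self):
        elective = profile_distribution(
            _calls({ProfileLabel.NKP44_1_DOMINANT: 6, ProfileLabel.NKP44_2_3: 1}), "e"
        )
        spontaneous = profile_distribution(
            _calls({ProfileLabel.NKP44_1_DOMINANT: 5, ProfileLabel.NKP44_2_3: 16}), "s"
        )
        table, result = compare_groups(elective, spontaneous)
        assert (table.a, table.b, table.c, table.d) == (6, 1, 5, 16)
        assert result.p_value == pytest.approx(0.00691, abs=5e-6)
        assert result.p_value <= 0.05

    def test_identical_distributions_p_one(self):
        d = profile_distribution(
            _calls({ProfileLabel.NKP44_1_DOMINANT: 5, ProfileLabel.NKP44_2_3: 5}), "g"
        )
        _, result = compare_groups(d, d)
        assert result.p_value == 1.0

    def test_incidence_comparison(self):
        a = incidence(_calls({ProfileLabel.NKP44_1_DOMINANT: 9, ProfileLabel.NEGATIVE: 1}), "a")
        b = incidence(_calls({ProfileLabel.NKP44_1_DOMINANT: 2, ProfileLabel.NEGATIVE: 8}), "b")
        table, result = compare_groups(a, b)
        assert (table.a, table.b, table.c, table.d) == (9, 1, 2, 8)
        assert result.method is StatMethod.FISHER_EXACT_TWO_SIDED
        assert result.p_value < 0.05

    def test_single_category_rejected(self):
        d = profile_distribution(_calls({ProfileLabel.NKP44_1_DOMINANT: 5}), "g")
        with pytest.raises(ValueError, match="two categories"):
            compare_groups(d, d)
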