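"""TEM family: pooled TEM, %TEM, R, F-comparison."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from anthro_reliability.tem import (
    compare_tem,
    coefficient_of_reliability,
    pooled_tem,
    relative_tem,
    reliability_result,
)

from conftest import make_groups


def anova_within_ms(values_per_group):
    """Independent oracle: within mean square as the df-weighted mean of
    per-group sample variances (textbook pooled-variance identity)."""
    num = sum((len(v) - 1) * np.var(v, ddof=1) for v in values_per_group)
    den = sum(len(v) - 1 for v in values_per_group)
    return num / den


group_lists = st.lists(
    st.lists(st.floats(-50, 50), min_size=2, max_size=4).map(lambda v: [round(x, 3) for x in v]),
    min_size=1,
    max_size=10,
)


class TestPooledTem:
    def test_all_pairs_hand_example(self):
        # pairs with differences 0.1, -0.1, 0.2, 0.0 -> sqrt(0.06/8)
        pairs = [[10.0, 10.1], [10.0, 9.9], [10.0, 10.2], [10.0, 10.0]]
        assert pooled_tem(make_groups(pairs)) == pytest.approx(0.0866025, abs=1e-6)

    def test_unbalanced_hand_example(self):
        groups = [[10.0, 10.2, 10.4], [20.0, 20.0, 20.3]]
        assert pooled_tem(make_groups(groups)) == pytest.approx(0.1870829, abs=1e-6)

    def test_identical_replicates_give_zero(self):
        assert pooled_tem(make_groups([[5.0, 5.0], [7.1, 7.1, 7.1]])) == pytest.approx(0.0, abs=1e-12)

    def test_empty_set_is_undefined_marker(self):
        assert math.isnan(pooled_tem(make_groups([])))

    def test_singleton_group_is_caller_error(self):
        with pytest.raises(ValueError):
            pooled_tem(make_groups([[1.0]]))

    @given(group_lists)
    def test_matches_anova_within_ms(self, groups):
        tem = pooled_tem(make_groups(groups))
        expected = anova_within_ms([np.asarray(g) for g in groups])
        assert tem**2 == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @given(group_lists, st.floats(0.1, 100), st.floats(-1000, 1000))
    def test_scale_equivariance_and_shift_invariance(self, groups, c, a):
        base = pooled_tem(make_groups(groups))
        scaled = pooled_tem(make_groups([[c * x for x in g] for g in groups]))
        shifted = pooled_tem(make_groups([[x + a for x in g] for g in groups]))
        assert scaled == pytest.approx(c * base, rel=1e-9, abs=1e-9)
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-6)

    def test_all_pairs_reduction_identity(self, rng):
        pairs = rng.normal(50, 5, size=(40, 2))
        diffs = pairs[:, 1] - pairs[:, 0]
        classical = math.sqrt(np.sum(diffs**2) / (2 * len(pairs)))
        assert pooled_tem(make_groups(pairs.tolist())) == pytest.approx(classical, rel=1e-14)


class TestDerivedStatistics:
    def test_relative_tem(self):
        assert relative_tem(0.5, 25.0) == pytest.approx(2.0)
        assert relative_tem(0.0, 3.0) == 0.0
        # scale invariance: both scaled by 10
        assert relative_tem(5.0, 250.0) == relative_tem(0.5, 25.0)

    def test_relative_tem_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            relative_tem(0.5, 0.0)

    def test_coefficient_of_reliability(self):
        assert coefficient_of_reliability(0.1, 1.0) == pytest.approx(0.99)
        assert coefficient_of_reliability(0.0, 2.0) == 1.0
        assert coefficient_of_reliability(1.5, 1.5) == 0.0

    def test_negative_r_reported_with_warning(self):
        with pytest.warns(UserWarning, match="negative"):
            r = coefficient_of_reliability(2.0, 1.0)
        assert r == pytest.approx(-3.0)

    def test_zero_sd_undefined(self):
        with pytest.warns(UserWarning):
            assert math.isnan(coefficient_of_reliability(0.1, 0.0))

    def test_reliability_result_identities(self, rng):
        groups = make_groups(rng.normal(30, 4, size=(12, 3)).round(1).tolist())
        res = reliability_result(groups)
        values = groups.values()
        assert res.n == 36
        assert res.pct_tem == 100.0 * res.tem / res.grand_mean
        assert res.r_coef == 1.0 - res.tem**2 / res.between_subject_sd**2
        assert res.grand_mean == pytest.approx(values.mean())

    def test_empty_stratum_gives_undefined_row(self):
        res = reliability_result(make_groups([]))
        assert res.n == 0 and math.isnan(res.tem) and math.isnan(res.pct_tem)


class TestCompareTem:
    def test_study_scale_example(self):
        # site leads 0.097 vs fieldworkers 0.291: F = (0.097/0.291)^2 = 1/9
        cmp = compare_tem(0.097, 33, 0.291, 246)
        assert cmp.f_stat == pytest.approx(1.0 / 9.0, abs=1e-5)
        assert 0 <= cmp.p_value <= 1

    def test_null_case(self):
        cmp = compare_tem(0.2, 10, 0.2, 10)
        assert cmp.f_stat == 1.0
        assert cmp.p_value == pytest.approx(1.0)

    def test_simple_ratio(self):
        assert compare_tem(0.2, 5, 0.1, 5).f_stat == pytest.approx(4.0)

    def test_symmetry_of_two_sided_p(self):
        a = compare_tem(0.3, 20, 0.2, 30)
        b = compare_tem(0.2, 30, 0.3, 20)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.f_stat == pytest.approx(1.0 / b.f_stat, rel=1e-12)

    def test_zero_tem_undefined(self):
        cmp = compare_tem(0.0, 5, 0.1, 5)
        assert math.isnan(cmp.f_stat) and math.isnan(cmp.p_value)

    def test_null_pvalues_uniform(self, rng):
        """Under equal error variances the variance-ratio pivot is exact,
        so null p-values are uniform (KS check on simulated exercises)."""
        n_sim, n_a, n_b, sigma = 1000, 60, 90, 0.5
        pvals = np.empty(n_sim)
        for s in range(n_sim):
            d_a = rng.normal(0, sigma * math.sqrt(2), n_a)
            d_b = rng.normal(0, sigma * math.sqrt(2), n_b)
            tem_a = math.sqrt(np.sum(d_a**2) / (2 * n_a))
            tem_b = math.sqrt(np.sum(d_b**2) / (2 * n_b))
            pvals[s] = compare_tem(tem_a, n_a, tem_b, n_b).p_value
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.08
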