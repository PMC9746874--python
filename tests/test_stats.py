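import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from heartde.errors import ValidationError
from heartde.stats import (
    bh_adjust,
    combine_fisher,
    estimate_df,
    location_test,
    proportion_test,
    q_to_pvalue,
    scale_test,
)


class TestProportionTest:
    def test_equal_proportions_give_no_evidence(self):
        z, L1 = proportion_test(5, 10, 5, 10)
        assert z == 0.0 and L1 == 1.0

    def test_worked_example(self):
        # pooled p* = 0.5, se = sqrt(0.25 * 0.2)
        z, L1 = proportion_test(8, 10, 2, 10)
        assert z == pytest.approx(0.6 / np.sqrt(0.05), rel=1e-12)
        assert z == pytest.approx(2.683281573, rel=1e-9)
        assert L1 == pytest.approx(0.0072903581, rel=1e-7)

    @pytest.mark.parametrize("m", [0, 10])
    def test_degenerate_pooled_proportion(self, m):
        z, L1 = proportion_test(m, 10, m, 10)
        assert z == 0.0 and L1 == 1.0

    def test_m_exceeding_n_rejected(self):
        with pytest.raises(ValidationError):
            proportion_test(11, 10, 2, 10)

    @given(
        m1=st.integers(0, 30),
        n1=st.integers(1, 30),
        m2=st.integers(0, 30),
        n2=st.integers(1, 30),
    )
    @settings(max_examples=200, deadline=None)
    def test_group_swap_symmetry(self, m1, n1, m2, n2):
        m1, m2 = min(m1, n1), min(m2, n2)
        z_a, L_a = proportion_test(m1, n1, m2, n2)
        z_b, L_b = proportion_test(m2, n2, m1, n1)
        assert z_a == pytest.approx(-z_b, abs=1e-12)
        assert L_a == pytest.approx(L_b, rel=1e-12)


class TestLocationTest:
    def test_identical_samples(self):
        t, df, L2 = location_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and L2 == 1.0

    def test_worked_example_equal_variances(self):
        t, df, L2 = location_test([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert t == pytest.approx(-5.0, rel=1e-12)
        assert df == pytest.approx(8.0, rel=1e-12)
        assert L2 == pytest.approx(0.00105283, rel=1e-5)

    def test_zero_variance_equal_means(self):
        t, df, L2 = location_test([2, 2, 2], [2, 2, 2])
        assert t == 0.0 and L2 == 1.0

    def test_zero_variance_different_means_clamped(self):
        t, df, L2 = location_test([2, 2, 2], [3, 3, 3])
        assert L2 == pytest.approx(1e-300)
        assert t == -np.inf

    def test_zeros_rejected(self):
        with pytest.raises(ValidationError):
            location_test([0, 1, 2], [1, 2, 3])


class TestScaleTest:
    def test_identical_dispersion(self):
        W, L3 = scale_test([1, 2, 3], [1, 2, 3])
        assert W == 0.0 and L3 == 1.0

    def test_worked_example(self):
        # medians 3 and 3; mean abs deviations 1.2 and 1.6
        W, L3 = scale_test([1, 2, 3, 4, 5], [1, 1, 3, 5, 5])
        assert W == pytest.approx(8 * 0.4 / 6.0, rel=1e-12)
        assert L3 == pytest.approx(0.48604, rel=1e-4)

    def test_strong_dispersion_difference(self):
        W, L3 = scale_test([1, 1, 1, 1], [1, 9, 1, 9])
        assert W > 10 and L3 < 0.05

    def test_constant_groups_different_spread_clamped(self):
        # deviations all zero within groups but unequal between: clamp
        W, L3 = scale_test([5, 5, 5, 5], [1, 9, 9, 1])
        assert np.isinf(W) and L3 == pytest.approx(1e-300)


class TestCombineFisher:
    def test_no_evidence_is_zero(self):
        assert combine_fisher([1.0, 1.0, 1.0]) == 0.0

    def test_direct_formula(self):
        assert combine_fisher([0.05] * 3) == pytest.approx(-6 * np.log(0.05), rel=1e-14)

    def test_combines_worked_component_examples(self):
        _, L1 = proportion_test(8, 10, 2, 10)
        _, _, L2 = location_test([1, 2, 3, 4, 5], [1, 2, 4, 4, 5])
        _, L3 = scale_test([1, 2, 3, 4, 5], [1, 1, 3, 5, 5])
        Q = combine_fisher([L1, L2, L3])
        assert Q == pytest.approx(-2 * (np.log(L1) + np.log(L2) + np.log(L3)), rel=1e-14)

    def test_invalid_components_excluded(self):
        full = combine_fisher([0.1, 0.2, 0.3])
        masked = combine_fisher([0.1, 0.2, 0.3], valid_mask=[True, False, True])
        assert masked == pytest.approx(-2 * (np.log(0.1) + np.log(0.3)))
        assert masked < full

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValidationError):
            combine_fisher([0.0, 0.5, 0.5])

    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=3))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_component(self, L):
        Q = combine_fisher(L)
        for i in range(len(L)):
            smaller = list(L)
            smaller[i] = L[i] / 2
            assert combine_fisher(smaller) > Q


class TestQToPvalue:
    def test_zero_statistic(self):
        assert q_to_pvalue(0.0, 6.0) == 1.0

    def test_chi2_critical_value(self):
        assert q_to_pvalue(12.59, 6.0) == pytest.approx(0.050, abs=5e-4)

    def test_large_q_clamped_above_zero(self):
        p = q_to_pvalue(1e6, 6.0)
        assert 0 < p <= 1e-300

    def test_strictly_decreasing_in_q(self):
        qs = np.linspace(0, 50, 100)
        ps = q_to_pvalue(qs, 4.5)
        assert np.all(np.diff(ps) < 0)


class TestEstimateDf:
    @pytest.mark.parametrize("d", [3, 4, 5, 6])
    def test_parameter_recovery(self, d):
        rng = np.random.default_rng(d)
        est = estimate_df(rng.chisquare(d, 10000))
        assert est == pytest.approx(d, abs=0.15)

    def test_few_values_fall_back_to_six(self, caplog):
        assert estimate_df(np.full(10, 3.0)) == 6.0

    def test_contamination_resistance(self):
        # 5% of values replaced by a heavy DE-like tail must not drag df up
        rng = np.random.default_rng(99)
        Q = rng.chisquare(4, 10000)
        Q[:500] = rng.chisquare(4, 500) + 80.0
        assert estimate_df(Q) == pytest.approx(4.0, abs=0.3)


class TestBhAdjust:
    def test_by_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value(self):
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    def test_ties_at_full_rank(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_matches_reference_implementation(self, p):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, ref, rtol=1e-12)
        assert np.all(ours >= np.asarray(p) - 1e-15)


class TestComponentReferenceEquivalence:
    def test_matches_independent_implementations_on_random_inputs(self):
        """Each component equals its reference on 200 random small inputs."""
        import statsmodels.stats.proportion as smp

        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(2, 40, 2)
            m1 = int(rng.integers(1, n1))
            m2 = int(rng.integers(1, n2))
            z, L1 = proportion_test(m1, n1, m2, n2)
            z_ref, p_ref = smp.proportions_ztest([m1, m2], [n1, n2])
            assert z == pytest.approx(z_ref, rel=1e-10, abs=1e-12)
            assert L1 == pytest.approx(p_ref, rel=1e-10, abs=1e-12)

            x1 = rng.integers(1, 20, int(rng.integers(3, 25))).astype(float)
            x2 = rng.integers(1, 20, int(rng.integers(3, 25))).astype(float)
            t, _, L2 = location_test(x1, x2)
            ref = sps.ttest_ind(x1, x2, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10, abs=1e-12)
            assert L2 == pytest.approx(ref.pvalue, rel=1e-10, abs=1e-300)

            W, L3 = scale_test(x1, x2)
            ref = sps.levene(x1, x2, center="median")
            assert W == pytest.approx(ref.statistic, rel=1e-10, abs=1e-12)
            assert L3 == pytest.approx(ref.pvalue, rel=1e-10, abs=1e-300)
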