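"""Tests for relative expression and the two-sample / correlation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import exprsurv as es
from exprsurv.expression import DegenerateStatisticError
from exprsurv.survival import ValidationError


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "ct_t, ct_r, expected",
        [(25.0, 25.0, 1.0), (26.0, 25.0, 0.5), (23.0, 25.0, 4.0)],
    )
    def test_delta_ct_rule(self, ct_t, ct_r, expected):
        assert es.relative_expression(ct_t, ct_r) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=5, max_value=40),
        st.floats(min_value=5, max_value=40),
        st.floats(min_value=0.01, max_value=5),
    )
    def test_monotone_in_both_cts(self, ct_t, ct_r, delta):
        base = es.relative_expression(ct_t, ct_r)
        assert es.relative_expression(ct_t + delta, ct_r) < base
        assert es.relative_expression(ct_t, ct_r + delta) > base

    def test_invalid_ct_rejected(self):
        with pytest.raises(ValidationError):
            es.relative_expression(float("nan"), 25.0)
        with pytest.raises(ValidationError):
            es.relative_expression(-1.0, 25.0)

    def test_donor_median_rescaling(self):
        donors = [0.5, 1.0, 2.0]
        out = es.rescale_to_reference_median([1.0, 2.0], donors)
        np.testing.assert_allclose(out, [1.0, 2.0])


class TestMannWhitney:
    def test_exact_small_example(self):
        # C(4,2)=6 equally likely rank assignments; both extremes counted
        r = es.mann_whitney_u([1, 2], [3, 4])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        r = es.mann_whitney_u([1, 2, 2, 5], [1, 2, 2, 5], mode="exact")
        assert r.p_value == 1.0

    def test_exact_matches_established_implementation(self, rng):
        for _ in range(25):
            n, m = rng.integers(2, 9, size=2)
            x = rng.permutation(np.arange(1.0, n + m + 1))  # no ties
            a, b = x[:n], x[n:]
            mine = es.mann_whitney_u(a, b, mode="exact")
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)
            assert mine.statistic == ref.statistic

    def test_exact_and_normal_approx_converge(self, rng):
        # no-tie samples at n=m=10: approximations agree within 0.01
        for _ in range(20):
            x = rng.permutation(np.arange(1.0, 21.0))
            a, b = x[:10], x[10:]
            p_exact = es.mann_whitney_u(a, b, mode="exact").p_value
            p_norm = es.mann_whitney_u(a, b, mode="normal_approx").p_value
            assert abs(p_exact - p_norm) <= 0.01

    def test_group_swap_symmetry(self, rng):
        a, b = rng.normal(size=12), rng.normal(1.0, 1.0, 15)
        r1 = es.mann_whitney_u(a, b)
        r2 = es.mann_whitney_u(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert r1.statistic + r2.statistic == pytest.approx(a.size * b.size)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            es.mann_whitney_u([], [1.0])


class TestStudentT:
    def test_identical_samples_null(self):
        r = es.student_t([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_pooled_t_closed_form(self):
        # equal variance, shift +10: t = d / (s_p * sqrt(2/n))
        x = np.array([1.0, 2.0, 3.0])
        y = x + 10.0
        r = es.student_t(x, y, variant="pooled")
        sp = np.sqrt(((x.var(ddof=1)) * 2 + (y.var(ddof=1)) * 2) / 4)
        t_expected = -10.0 / (sp * np.sqrt(2 / 3))
        assert r.statistic == pytest.approx(t_expected)
        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(t_expected), 4))

    def test_welch_equals_pooled_under_equal_variance_and_size(self, rng):
        x = rng.normal(size=10)
        y = x[::-1] + 1.0  # identical sample variance, equal n
        a = es.student_t(x, y, variant="welch")
        b = es.student_t(x, y, variant="pooled")
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.detail["df"] == pytest.approx(b.detail["df"], abs=1e-9)

    def test_double_zero_variance_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            es.student_t([2.0, 2.0], [3.0, 3.0])


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert es.spearman_corr(x, [2.0, 4.0, 9.0, 16.0]).statistic == pytest.approx(1.0)
        assert es.spearman_corr(x, [5.0, 4.0, 2.0, 1.0]).statistic == pytest.approx(-1.0)

    def test_tied_case_matches_established_implementation(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0])
        mine = es.spearman_corr(x, y)
        ref = stats.spearmanr(x, y)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            es.spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareGroups:
    def _two_group_frame(self, rng, shift, n_a=39, n_b=12):
        import pandas as pd

        a = np.exp(rng.normal(-1.1, 0.9, n_a))
        b = np.exp(rng.normal(-1.1 + shift, 0.9, n_b))
        return pd.DataFrame(
            {
                "cohort": ["AML"] * n_a + ["donor"] * n_b,
                "relative_expression": np.concatenate([a, b]),
            }
        )

    def test_detects_simulated_cohort_shift(self):
        # AML-vs-donor style shift (donor median ~3x higher), n = 39 vs 12
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = self._two_group_frame(rng, shift=np.log(0.95 / 0.33))
            comp = es.compare_groups(df, "cohort", test="mannwhitney")[0]
            hits += comp.p_value < 0.05
        assert hits >= 95

    def test_null_rejection_rate_near_alpha(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            df = self._two_group_frame(rng, shift=0.0)
            comp = es.compare_groups(df, "cohort", test="mannwhitney")[0]
            hits += comp.p_value < 0.05
        assert 0.01 <= hits / n_seeds <= 0.10

    def test_single_identical_values_per_group(self):
        import pandas as pd

        df = pd.DataFrame({"grp": ["a", "b"], "relative_expression": [0.4, 0.4]})
        comp = es.compare_groups(df, "grp")[0]
        assert comp.p_value == 1.0
        assert comp.median_a == comp.median_b == 0.4

    def test_merge_levels_collapses_risk_groups(self, rng):
        import pandas as pd

        df = pd.DataFrame(
            {
                "eln2017": ["favorable"] * 10 + ["intermediate"] * 10 + ["adverse"] * 10,
                "relative_expression": np.exp(rng.normal(-1.1, 0.9, 30)),
            }
        )
        comps = es.compare_groups(
            df, "eln2017", merge_levels={"int_adv": ["intermediate", "adverse"]}
        )
        assert len(comps) == 1
        assert {comps[0].group_a, comps[0].group_b} == {"favorable", "int_adv"}

    def test_single_level_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"grp": ["a", "a"], "relative_expression": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            es.compare_groups(df, "grp")

    def test_stars_convention(self):
        assert es.significance_stars(0.2) == "ns"
        assert es.significance_stars(0.03) == "*"
        assert es.significance_stars(0.004) == "**"
        assert es.significance_stars(5e-4) == "***"
        assert es.significance_stars(5e-5) == "****"
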