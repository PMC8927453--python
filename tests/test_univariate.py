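"""Decision-tree comparisons, Cohen's d, and noncentral-t power analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burnmech.errors import UndefinedEffectSizeError, UntestableError
from burnmech.univariate import (PowerSpec, cohens_d, decision_tree_compare,
                                 pooled_cohens_d, required_sample_sizes,
                                 t_test_power)


class TestDecisionTree:
    def test_normal_null_routes_through_t_test(self):
        rng = np.random.default_rng(0)
        reject = 0
        t_routed = 0
        n_rep = 200
        for _ in range(n_rep):
            res = decision_tree_compare(rng.normal(size=50), rng.normal(size=50), 0.01)
            reject += res.reject
            names = [s.test for s in res.path]
            if "f_test_equal_variances" in names and res.final_test in (
                    "t_test_pooled", "t_test_welch"):
                t_routed += 1
        # normality holds, so nearly every replicate takes the parametric branch
        assert t_routed >= 0.95 * n_rep
        assert reject <= 0.05 * n_rep  # null: rejections stay rare at alpha=0.01

    def test_overwhelming_separation(self):
        rng = np.random.default_rng(1)
        res = decision_tree_compare(rng.normal(0, 1, 30), rng.normal(5, 1, 30), 0.01)
        assert res.reject and res.final_p < 1e-6

    def test_shifted_exponential_routes_to_rank_sum(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(size=80)
        y = rng.exponential(size=60) + 3.0  # same shape, shifted location
        res = decision_tree_compare(x, y, 0.01)
        names = [s.test for s in res.path]
        assert "ks_shape" in names
        assert res.final_test == "wilcoxon_rank_sum"
        assert res.reject

    def test_path_is_deterministic(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert decision_tree_compare(x, y, 0.01) == decision_tree_compare(x, y, 0.01)

    def test_reject_flag_consistent_with_p(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            res = decision_tree_compare(rng.normal(size=20), rng.normal(0.5, 1, 20), 0.05)
            assert res.reject == (res.final_p < res.alpha)
            assert 0 <= res.final_p <= 1

    def test_tied_data_uses_asymptotic_rank_sum(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 4, size=40).astype(float)
        y = rng.integers(1, 5, size=40).astype(float)
        res = decision_tree_compare(x, y, 0.01)
        assert 0 <= res.final_p <= 1

    def test_exponential_null_type_one_error(self):
        """Full-tree rejection rate under a skewed null stays near alpha."""
        rng = np.random.default_rng(6)
        n_rep = 4000
        rejections = sum(
            decision_tree_compare(rng.exponential(size=95),
                                  rng.exponential(size=38), 0.01).reject
            for _ in range(n_rep))
        rate = rejections / n_rep
        se = np.sqrt(0.01 * 0.99 / n_rep)
        assert abs(rate - 0.01) <= 3 * se

    def test_untestable_inputs(self):
        with pytest.raises(UntestableError):
            decision_tree_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0], 0.01)
        with pytest.raises(UntestableError):
            decision_tree_compare([1.0] * 10, [1.0] * 10, 0.01)


class TestCohensD:
    def test_unit_variance_construction(self):
        s = 1 / np.sqrt(2)
        x = np.array([-s, s])            # mean 0, sample SD exactly 1
        y = x + 1.4                      # mean 1.4, sample SD exactly 1
        assert cohens_d(x, y) == pytest.approx(1.4)

    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x) == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        y = np.array([3.0, 4.0, 6.0])
        assert cohens_d(c * x, c * y) == pytest.approx(cohens_d(x, y), rel=1e-9)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(UndefinedEffectSizeError):
            cohens_d([2.0, 2.0], [3.0, 3.0])


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert t_test_power(0.0, 20, 20, 0.05) == pytest.approx(0.05, rel=1e-9)
        assert t_test_power(0.0, 95, 38, 0.01) == pytest.approx(0.01, rel=1e-9)

    def test_monotone_in_sample_size(self):
        powers = [t_test_power(0.8, n, 2 * n, 0.01) for n in range(5, 60, 5)]
        assert np.all(np.diff(powers) > 0)

    def test_against_monte_carlo_oracle(self):
        """Exact noncentral-t power vs a 1e5-replicate simulated t-test."""
        d, n1, n2, alpha = 1.4, 18, 45, 0.01
        rng = np.random.default_rng(42)
        reps = 100_000
        x = rng.normal(d, 1.0, size=(reps, n1))
        y = rng.normal(0.0, 1.0, size=(reps, n2))
        vx = x.var(axis=1, ddof=1)
        vy = y.var(axis=1, ddof=1)
        sp = np.sqrt(((n1 - 1) * vx + (n2 - 1) * vy) / (n1 + n2 - 2))
        t = (x.mean(axis=1) - y.mean(axis=1)) / (sp * np.sqrt(1 / n1 + 1 / n2))
        from scipy.stats import t as t_dist
        t_crit = t_dist.ppf(1 - alpha / 2, n1 + n2 - 2)
        p_mc = np.mean(np.abs(t) > t_crit)
        p_exact = t_test_power(d, n1, n2, alpha)
        se = np.sqrt(p_mc * (1 - p_mc) / reps)
        assert abs(p_mc - p_exact) <= 3 * se


class TestRequiredSampleSizes:
    def test_reference_calculator_case(self):
        """d=1.4, alpha=0.01, power=0.99, ratio 2.5 -> groups of 18 and 46."""
        n_small, n_large = required_sample_sizes(
            PowerSpec(d=1.4, alpha=0.01, power=0.99, allocation_ratio=2.5))
        assert n_small == 18
        assert n_large == 46

    def test_balanced_textbook_case(self):
        n_small, n_large = required_sample_sizes(
            PowerSpec(d=0.5, alpha=0.05, power=0.80, allocation_ratio=1.0))
        assert (n_small, n_large) == (64, 64)

    def test_larger_effect_never_needs_more_samples(self):
        spec = dict(alpha=0.01, power=0.99, allocation_ratio=2.5)
        n_d = required_sample_sizes(PowerSpec(d=1.4, **spec))[0]
        n_2d = required_sample_sizes(PowerSpec(d=2.8, **spec))[0]
        assert n_2d <= n_d

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(d=-1.0)
        with pytest.raises(ValueError):
            PowerSpec(d=1.0, alpha=0.5, power=0.2)


def test_pooled_cohens_d_averages_per_property(rng):
    import pandas as pd
    n = 50
    df = pd.DataFrame({
        "a": np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)]),
        "b": np.concatenate([rng.normal(0, 1, n), rng.normal(0, 1, n)]),
    })
    labels = np.array(["x"] * n + ["y"] * n)
    expected = np.mean([cohens_d(df.loc[labels == "x", c], df.loc[labels == "y", c])
                        for c in ("a", "b")])
    assert pooled_cohens_d(df, labels, ("a", "b")) == pytest.approx(expected)
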