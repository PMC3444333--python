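"""Component tests: pooled t, Mann-Whitney U, Shapiro-Wilk.

Oracles: hand-evaluated pooled-t statistic, brute-force enumeration of
the U permutation distribution, scipy's implementations.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pretestsim import (
    DegenerateSampleError,
    SamplePair,
    UnsupportedSampleSizeError,
    mann_whitney_u,
    shapiro_wilk,
    t_test_pooled,
)
from pretestsim._mwu import exact_two_sided_p, null_pmf
from pretestsim._shapiro import shapiro_w_p

floats_mid = st.floats(-50, 50, allow_nan=False, width=64)


@st.composite
def equal_pairs(draw, min_size=3, max_size=6):
    """Two equal-length samples with a tie-free pooled set (values on a
    1e-3 grid, so shifts cannot create or destroy ties)."""
    n = draw(st.integers(min_size, max_size))
    grid = st.integers(-50_000, 50_000).map(lambda k: k / 1000.0)
    pooled = draw(st.lists(grid, min_size=2 * n, max_size=2 * n, unique=True))
    return np.array(pooled[:n]), np.array(pooled[n:])


def brute_force_u_p(x, y):
    """Two-sided p of U by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    m, total = len(x), len(x) + len(y)

    def u_of(xs, ys):
        return sum(
            1.0 if xi > yj else 0.5 if xi == yj else 0.0
            for xi in xs for yj in ys
        )

    u_obs = u_of(x, y)
    us = []
    for idx in itertools.combinations(range(total), m):
        mask = np.zeros(total, dtype=bool)
        mask[list(idx)] = True
        us.append(u_of(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_lo, p_hi))


class TestPooledT:
    def test_identical_samples_give_t_zero(self):
        r = t_test_pooled(SamplePair(np.array([1.0, 2, 3]), np.array([1.0, 2, 3])))
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # pooled s^2 = 5/3, T = -2/sqrt(5/6), df = 6
        r = t_test_pooled(SamplePair(np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6])))
        assert r.statistic == pytest.approx(-2.1909, abs=1e-4)
        assert r.df_or_n == 6
        assert r.p_value == pytest.approx(0.0709, abs=1e-4)

    def test_constant_pair_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            t_test_pooled(SamplePair(np.full(4, 2.0), np.full(4, 2.0)))

    @given(pair=equal_pairs())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_swap_negates_t_keeps_p(self, pair):
        x, y = pair
        a = t_test_pooled(SamplePair(x, y))
        b = t_test_pooled(SamplePair(y, x))
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    @given(pair=equal_pairs(), c=st.floats(0.01, 100, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, pair, c):
        x, y = pair
        a = t_test_pooled(SamplePair(x, y))
        b = t_test_pooled(SamplePair(c * x, c * y))
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=12), rng.exponential(size=12)
            r = t_test_pooled(SamplePair(x, y))
            s = stats.ttest_ind(x, y, equal_var=True)
            assert r.statistic == pytest.approx(s.statistic, rel=1e-12)
            assert r.p_value == pytest.approx(s.pvalue, rel=1e-12)


class TestMannWhitneyU:
    def test_extreme_separation(self):
        r = mann_whitney_u(SamplePair(np.array([1.0, 2, 3]), np.array([4.0, 5, 6])),
                           mode="exact")
        # x entirely below y: U = 0; enumeration over C(6,3)=20 splits
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 20)

    def test_center_of_null_distribution(self):
        r = mann_whitney_u(SamplePair(np.array([1.0, 4, 6]), np.array([2.0, 3, 5])),
                           mode="exact")
        assert r.p_value == pytest.approx(1.0)

    @given(pair=equal_pairs(), shift=st.floats(-100, 100, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shift_invariance(self, pair, shift):
        x, y = pair
        a = mann_whitney_u(SamplePair(x, y))
        b = mann_whitney_u(SamplePair(x + shift, y + shift))
        assert a.statistic == b.statistic
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    @given(pair=equal_pairs())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exact_mode_equals_brute_force(self, pair):
        x, y = pair
        u_ref, p_ref = brute_force_u_p(x, y)
        r = mann_whitney_u(SamplePair(x, y), mode="exact")
        assert r.statistic == pytest.approx(u_ref)
        assert r.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_exact_null_pmf_sums_to_one(self):
        for m, n in [(3, 3), (5, 4), (10, 10)]:
            pmf = null_pmf(m, n)
            assert pmf.sum() == pytest.approx(1.0)
            assert pmf.size == m * n + 1
            assert np.allclose(pmf, pmf[::-1])  # symmetry about mn/2

    def test_exact_table_matches_scipy(self, rng):
        for n in [5, 10, 20]:
            x, y = rng.normal(size=n), rng.normal(size=n)
            r = mann_whitney_u(SamplePair(x, y), mode="exact")
            s = stats.mannwhitneyu(x, y, method="exact")
            table = exact_two_sided_p(n, n)
            assert table[int(s.statistic)] == pytest.approx(s.pvalue, rel=1e-12)
            assert r.p_value == pytest.approx(s.pvalue, rel=1e-12)

    def test_normal_approx_matches_scipy_with_ties(self, rng):
        for _ in range(10):
            x = np.round(rng.normal(size=30), 1)  # induces ties
            y = np.round(rng.normal(size=30), 1)
            r = mann_whitney_u(SamplePair(x, y), mode="normal_approx")
            s = stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
            assert r.statistic == pytest.approx(s.statistic)
            assert r.p_value == pytest.approx(s.pvalue, rel=1e-10)

    def test_auto_uses_exact_below_50_and_approx_above(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        auto = mann_whitney_u(SamplePair(x, y))
        assert auto.p_value == pytest.approx(
            mann_whitney_u(SamplePair(x, y), mode="exact").p_value)
        x, y = rng.normal(size=30), rng.normal(size=30)
        auto = mann_whitney_u(SamplePair(x, y))
        assert auto.p_value == pytest.approx(
            mann_whitney_u(SamplePair(x, y), mode="normal_approx").p_value)

    def test_ties_fall_back_to_approximation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 5.0, 6.0])
        r = mann_whitney_u(SamplePair(x, y), mode="auto")
        ref = mann_whitney_u(SamplePair(x, y), mode="normal_approx")
        assert r.p_value == pytest.approx(ref.p_value)


class TestShapiroWilk:
    def test_matches_scipy_reference(self, rng):
        """Royston AS R94 agreement with an established implementation."""
        worst = 0.0
        for n in [3, 4, 5, 6, 8, 11, 12, 20, 30, 50, 100, 500]:
            for gen in (rng.normal, rng.exponential, lambda size: rng.uniform(size=size)):
                x = gen(size=n)
                r = shapiro_wilk(x)
                ref_w, ref_p = stats.shapiro(x)
                worst = max(worst, abs(r.statistic - ref_w))
                assert r.statistic == pytest.approx(ref_w, abs=1e-4)
                assert r.p_value == pytest.approx(ref_p, abs=1e-4)
        assert worst < 1e-6

    @given(a=st.floats(0.01, 100), b=st.floats(-100, 100))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_location_scale_invariance(self, a, b):
        x = np.array([0.3, -1.2, 2.5, 0.7, -0.4, 1.9, -2.2, 0.05])
        r1 = shapiro_wilk(x)
        r2 = shapiro_wilk(a * x + b)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-6, abs=1e-12)

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk(np.full(10, 3.0))

    @pytest.mark.parametrize("n", [2, 5001])
    def test_unsupported_sizes(self, n):
        with pytest.raises(UnsupportedSampleSizeError):
            shapiro_wilk(np.linspace(0, 1, n))

    def test_null_pvalues_approximately_uniform(self, rng):
        """Kolmogorov distance of the null p-value distribution at n=30."""
        _, p = shapiro_w_p(rng.normal(size=(100_000, 30)))
        d = stats.kstest(p, "uniform").statistic
        assert d < 0.02

    def test_batch_kernel_matches_scalar(self, rng):
        x = rng.exponential(size=(50, 25))
        w, p = shapiro_w_p(x)
        for i in range(50):
            r = shapiro_wilk(x[i])
            assert r.statistic == pytest.approx(w[i], rel=1e-12)
            assert r.p_value == pytest.approx(p[i], rel=1e-12)
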