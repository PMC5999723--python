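"""Switching statistics: extremum fits, bootstrap, hinge/AIC, divergence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from gripswitch.stats import (
    acc_sign_threshold,
    aic_ls,
    bootstrap_diff,
    divergence_time,
    fit_extremum,
    piecewise_fit,
    threshold_correlation,
)


class TestFitExtremum:
    def test_inverted_parabola_peak_recovered(self):
        x = np.linspace(3.5, 7.9, 41)
        c = 5.2
        y = -((x - c) ** 2)
        fit = fit_extremum(x, y)
        assert fit.x_star == pytest.approx(c, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_noiseless_quartic_interior_argmax(self):
        # oracle: dense grid evaluation of the generating quartic
        x = np.linspace(3.5, 7.9, 41)
        coef = [-1.0, 21.0, -160.0, 520.0, -600.0]  # quartic in x
        y = np.polyval(coef, x)
        grid = np.linspace(x.min(), x.max(), 2_000_001)
        expected = grid[np.argmax(np.polyval(coef, grid))]
        fit = fit_extremum(x, y)
        assert not fit.at_boundary
        assert fit.x_star == pytest.approx(expected, abs=1e-4)

    def test_boundary_maximum_flagged(self):
        x = np.linspace(0.0, 1.0, 20)
        fit = fit_extremum(x, 2.0 * x)  # increasing: max at the edge
        assert fit.at_boundary and fit.x_star == pytest.approx(1.0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_extremum([1, 2, 3], [1, 2, 3])


class TestBootstrap:
    def test_identical_samples_give_degenerate_ci(self):
        a = np.arange(18.0)
        ci = bootstrap_diff(a, a, reps=1000, seed=0)
        assert ci.lo == ci.hi == 0.0
        assert not ci.excludes_zero

    def test_constant_shift_gives_point_ci(self):
        a = np.full(18, 2.0)
        ci = bootstrap_diff(a + 1.0, a, reps=1000, seed=0)
        assert ci.lo == ci.hi == pytest.approx(1.0)
        assert ci.excludes_zero

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_diff([1, 2], [1, 2], reps=1000)
        with pytest.raises(ValueError):
            bootstrap_diff(np.ones(5), np.ones(5), reps=10)
        with pytest.raises(ValueError):
            bootstrap_diff(np.ones(5), np.ones(5), statistic="median")

    def test_coverage_of_true_mean_difference(self):
        # Monte-Carlo oracle: percentile CI covers the true difference 0.3
        # close to the nominal 95% rate for n = 18 paired participants
        rng = np.random.default_rng(20180607)
        covered = 0
        n_rep = 400
        for i in range(n_rep):
            a = rng.normal(0.3, 0.18, 18)
            b = rng.normal(0.0, 0.18, 18)
            ci = bootstrap_diff(a, b, reps=1000, seed=int(rng.integers(2**31)))
            covered += ci.lo <= 0.3 <= ci.hi
        assert 0.90 <= covered / n_rep <= 0.985

    def test_determinism(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=18), rng.normal(size=18)
        c1 = bootstrap_diff(a, b, reps=2000, seed=42)
        c2 = bootstrap_diff(a, b, reps=2000, seed=42)
        assert (c1.lo, c1.hi) == (c2.lo, c2.hi)


class TestPiecewiseFit:
    def test_collinear_data_gives_equal_slopes(self):
        x = np.linspace(3.0, 8.0, 30)
        y = 5.0 + 2.0 * x
        fit = piecewise_fit(x, y, xb=5.0)
        assert fit.s_lo == pytest.approx(2.0, abs=1e-9)
        assert fit.s_hi == pytest.approx(2.0, abs=1e-9)
        assert fit.rss_piecewise == pytest.approx(0.0, abs=1e-18)
        assert fit.rss_linear == pytest.approx(0.0, abs=1e-18)

    def test_exact_hinge_recovered(self):
        xb = 5.0
        x = np.linspace(3.5, 7.9, 41)
        y = 40.0 + 18.0 * np.minimum(x - xb, 0.0)  # s_lo=18, s_hi=0
        fit = piecewise_fit(x, y, xb)
        assert fit.s_lo == pytest.approx(18.0, abs=1e-9)
        assert fit.s_hi == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_rss_minimization(self):
        # oracle: numerically minimize the hinge RSS over its 3 parameters
        rng = np.random.default_rng(7)
        x = np.linspace(3.5, 7.9, 41)
        xb = 5.0
        y = 40.0 + 20.0 * np.minimum(x - xb, 0.0) + rng.normal(0, 3.0, x.size)

        def rss(p):
            b0, s_lo, s_hi = p
            pred = b0 + np.where(x < xb, s_lo * (x - xb), s_hi * (x - xb))
            return np.sum((y - pred) ** 2)

        res = minimize(rss, x0=[0.0, 0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        fit = piecewise_fit(x, y, xb)
        assert fit.intercept == pytest.approx(res.x[0], abs=1e-5)
        assert fit.s_lo == pytest.approx(res.x[1], abs=1e-5)
        assert fit.s_hi == pytest.approx(res.x[2], abs=1e-5)
        assert fit.rss_piecewise == pytest.approx(res.fun, rel=1e-9)

    def test_discontinuous_variant_has_four_params(self):
        rng = np.random.default_rng(1)
        x = np.linspace(3.5, 7.9, 41)
        y = rng.normal(size=41)
        cont = piecewise_fit(x, y, 5.0, continuous=True)
        disc = piecewise_fit(x, y, 5.0, continuous=False)
        assert disc.rss_piecewise <= cont.rss_piecewise + 1e-12

    def test_one_sided_breakpoint_rejected(self):
        x = np.linspace(5.5, 7.0, 10)
        with pytest.raises(ValueError):
            piecewise_fit(x, x, xb=5.0)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_hinge_never_fits_worse_than_line(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(3.0, 8.0, 24))
        x[:3], x[-3:] = x[:3] - 1.0, x[-3:] + 1.0  # both sides populated
        y = rng.normal(size=24)
        fit = piecewise_fit(x, y, xb=5.0)
        assert fit.rss_piecewise <= fit.rss_linear + 1e-9


class TestAic:
    def test_arithmetic_example(self):
        assert aic_ls(10, 10.0, 2) == pytest.approx(10 * math.log(1.0) + 6.0)

    def test_extra_parameter_costs_two(self):
        a1 = aic_ls(30, 12.0, 2)
        a2 = aic_ls(30, 12.0, 3)
        assert a2 - a1 == pytest.approx(2.0)

    def test_zero_rss_is_minus_inf_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert aic_ls(10, 0.0, 2) == -math.inf

    def test_small_sample_correction(self):
        n, rss, p = 12, 4.0, 3
        k = p + 1
        expected = n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert aic_ls(n, rss, p, corrected=True) == pytest.approx(expected)

    def test_line_data_prefers_line(self):
        # on straight-line data plus noise the hinge's extra slope is not
        # worth 2 AIC points in the clear majority of replicates
        rng = np.random.default_rng(20180607)
        x = np.linspace(3.5, 7.9, 41)
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            y = 3.0 + 5.0 * x + rng.normal(0, 2.0, x.size)
            fit = piecewise_fit(x, y, xb=5.0)
            wins += fit.aic_linear < fit.aic_piecewise
        assert wins / n_rep > 0.5


class TestDivergenceTime:
    def test_identical_matrices_never_diverge(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(10, 200))
        assert divergence_time(m, m.copy(), fs=500.0) is None

    def test_offset_from_40ms_detected_in_correct_bin(self):
        rng = np.random.default_rng(1)
        n_t = 200  # 400 ms at 500 Hz
        real = rng.normal(0, 0.01, (12, n_t))
        catch = rng.normal(0, 0.01, (12, n_t))
        catch[:, int(0.040 * 500):] += 1.0  # offset injected at exactly 40 ms
        assert divergence_time(real, catch, fs=500.0) == pytest.approx(40.0)

    def test_unsustained_blip_ignored(self):
        rng = np.random.default_rng(2)
        real = rng.normal(0, 0.01, (12, 200))
        catch = rng.normal(0, 0.01, (12, 200))
        catch[:, 10:20] += 1.0  # 20 ms blip only
        assert divergence_time(real, catch, fs=500.0) is None

    def test_mismatched_time_axes_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(np.zeros((3, 100)), np.zeros((3, 90)), fs=500.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(np.zeros((1, 100)), np.zeros((3, 100)), fs=500.0)


class TestAccSignThreshold:
    def test_linear_zero_crossing(self):
        lnk = np.linspace(3.5, 7.9, 41)
        acc = 5.0 - lnk
        assert acc_sign_threshold(lnk, acc) == pytest.approx(5.0, abs=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        lnk = np.repeat(np.linspace(3.5, 7.9, 41), 3)
        acc = 5.0 - lnk + rng.normal(0, 0.05, lnk.size)
        base = acc_sign_threshold(lnk, acc)
        perm = rng.permutation(lnk.size)
        assert acc_sign_threshold(lnk[perm], acc[perm]) == pytest.approx(base)

    def test_constant_sign_gives_none(self):
        lnk = np.linspace(3.5, 7.9, 10)
        assert acc_sign_threshold(lnk, np.ones(10)) is None


class TestThresholdCorrelation:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        r, p = threshold_correlation(x, x)
        assert r == pytest.approx(1.0)
        r, p = threshold_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_null_gives_small_r_on_average(self):
        rng = np.random.default_rng(20180607)
        rs, ps = [], []
        for _ in range(200):
            r, p = threshold_correlation(rng.normal(size=18),
                                         rng.normal(size=18))
            rs.append(r)
            ps.append(p)
        assert abs(np.mean(rs)) < 0.06
        # p-values roughly uniform: about 5% below 0.05
        assert 0.0 <= np.mean(np.array(ps) < 0.05) <= 0.12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            threshold_correlation(np.ones(10), np.arange(10.0))
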