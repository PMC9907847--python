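"""Distribution-core checks: closed forms against quadrature and reductions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from gtpd import GTPD, check_lr_order, gd
from tests.conftest import SCENARIO_PARAMS


# ---------------------------------------------------------------------------
# density, mixture, distribution functions
# ---------------------------------------------------------------------------


class TestPdf:
    def test_limit_at_zero(self):
        # lim_{x->0} f = theta^(k+1) b / (theta^k b + Gamma(k+1))
        assert GTPD(1, 1, 1.0).pdf(0.0) == pytest.approx(0.5, abs=1e-14)

    def test_exponential_reduction(self):
        law = GTPD(2, 0, 0.0)
        x = np.linspace(0, 5, 11)
        np.testing.assert_allclose(law.pdf(x), 2 * np.exp(-2 * x), rtol=1e-13)

    @pytest.mark.parametrize("theta,k", SCENARIO_PARAMS + [(0.6363, 3.1277)])
    def test_normalization(self, theta, k):
        law = gd(theta, k)
        total, _ = integrate.quad(law.pdf, 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GTPD(-1, 1)
        with pytest.raises(ValueError):
            GTPD(1, -0.5)
        with pytest.raises(ValueError):
            GTPD(1, 1, -2.0)
        with pytest.raises(ValueError):
            GTPD(1, 1).pdf(-0.1)


class TestMixture:
    def test_weight_examples(self):
        assert GTPD(1, 2, 0.0).mixture().z == 0.0  # pure gamma
        assert GTPD(1, 0, 1.0).mixture().z == pytest.approx(0.5)

    def test_recomposition_matches_direct_form(self):
        law = gd(2, 4)
        mix = law.mixture()
        x = np.linspace(1e-6, 8, 1000)
        assert np.max(np.abs(mix.pdf(x) - law.pdf(x))) < 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        theta=st.floats(0.1, 5.0),
        k=st.floats(0.0, 8.0),
        b=st.floats(0.0, 10.0),
        x=st.floats(1e-3, 20.0),
    )
    def test_recomposition_property(self, theta, k, b, x):
        law = GTPD(theta, k, b)
        assert law.mixture().pdf(x) == pytest.approx(law.pdf(x), rel=1e-10, abs=1e-300)


class TestCdf:
    def test_boundary_values(self):
        law = gd(1.5, 2.5)
        assert law.cdf(0.0) == 0.0
        assert law.cdf(1e6) == pytest.approx(1.0, abs=1e-12)

    def test_exponential_median(self):
        assert GTPD(1, 0, 0.0).cdf(math.log(2)) == pytest.approx(0.5, abs=1e-14)

    def test_matches_quadrature_of_pdf(self):
        law = gd(0.5, 1.5)
        for x in np.linspace(0.1, 12, 50):
            num, _ = integrate.quad(law.pdf, 0, x, limit=200)
            assert law.cdf(x) == pytest.approx(num, abs=1e-9)

    def test_sf_complements_cdf(self):
        law = gd(2, 4)
        x = np.linspace(0, 10, 200)
        np.testing.assert_allclose(law.cdf(x) + law.sf(x), 1.0, atol=1e-12)

    def test_derivative_is_pdf(self):
        law = gd(1.5, 2.5)
        x = np.linspace(0.2, 5, 40)
        h = 1e-6
        deriv = (law.cdf(x + h) - law.cdf(x - h)) / (2 * h)
        np.testing.assert_allclose(deriv, law.pdf(x), atol=1e-5)


class TestHazard:
    def test_exponential_constant_hazard(self):
        law = GTPD(2, 0, 0.0)
        np.testing.assert_allclose(law.hrf(np.linspace(0, 20, 30)), 2.0, rtol=1e-10)

    def test_hazard_limit_at_zero(self):
        # lim_{x->0} h = b theta^(k+1) / (Gamma(k+1) + b theta^k)
        assert GTPD(1, 1, 1.0).hrf(0.0) == pytest.approx(0.5, abs=1e-14)

    def test_equals_pdf_over_sf(self):
        law = gd(1.5, 2.5)
        x = np.linspace(0.05, 8, 100)
        np.testing.assert_allclose(law.hrf(x), law.pdf(x) / law.sf(x), rtol=1e-10)

    @pytest.mark.parametrize("theta,k", [(0.5, 0.3), (1.0, 1.0), (2.5, 0.5)])
    def test_nondecreasing_when_k_at_most_one(self, theta, k):
        law = gd(theta, k)
        x = np.linspace(0.01, law.quantile(0.999), 400)
        assert np.all(np.diff(law.hrf(x)) >= -1e-9)

    @pytest.mark.parametrize("theta,k", [(0.5, 1.5), (2.0, 4.0), (1.5, 2.5)])
    def test_bathtub_minimum_location(self, theta, k):
        # k > 1: hazard decreases then increases; the reported minimizer must
        # match a fine grid search and sit below the Glaser point
        law = gd(theta, k)
        rep = law.classify_shapes()
        grid = np.linspace(1e-4, law.quantile(0.99), 8000)
        argmin = grid[np.argmin(law.hrf(grid))]
        assert rep.hrf_min_location == pytest.approx(argmin, abs=2 * (grid[1] - grid[0]))
        assert rep.hrf_min_location < rep.glaser_point


# ---------------------------------------------------------------------------
# moments and related measures
# ---------------------------------------------------------------------------


class TestMoments:
    def test_zeroth_moment_is_one(self):
        for th, k in SCENARIO_PARAMS:
            assert gd(th, k).raw_moment(0) == pytest.approx(1.0, rel=1e-14)

    def test_exponential_mean(self):
        assert GTPD(4.0, 0, 0.0).raw_moment(1) == pytest.approx(0.25)

    @pytest.mark.parametrize("i", [1, 2, 3, 4, 5, 6])
    def test_closed_form_matches_quadrature(self, i):
        law = gd(2, 4)
        num, _ = integrate.quad(lambda x: x ** i * law.pdf(x), 0, np.inf, limit=200)
        assert law.raw_moment(i) == pytest.approx(num, rel=1e-6)

    def test_summary_measures_reductions(self):
        expo = GTPD(3.0, 0, 0.0).summary_measures()
        assert expo["variance"] == pytest.approx(1 / 9)
        assert expo["cv"] == pytest.approx(1.0)
        gamma21 = GTPD(1.0, 1.0, 0.0).summary_measures()  # gamma(2, 1)
        assert gamma21["mean"] == pytest.approx(2.0)
        assert gamma21["variance"] == pytest.approx(2.0)

    def test_summary_measures_from_raw_moments(self):
        law = gd(0.25, 0.5)
        m = [law.raw_moment(i) for i in range(5)]
        var = m[2] - m[1] ** 2
        got = law.summary_measures()
        assert got["mean"] == pytest.approx(m[1], abs=1e-10)
        assert got["variance"] == pytest.approx(var, abs=1e-10)
        assert got["skewness"] == pytest.approx(m[3] / var ** 1.5, abs=1e-10)
        assert got["kurtosis"] == pytest.approx(m[4] / var ** 2, abs=1e-10)
        assert got["cv"] == pytest.approx(math.sqrt(var) / m[1], abs=1e-10)

    def test_mgf(self):
        law = gd(2, 4)
        assert law.mgf(0.0) == pytest.approx(1.0)
        assert GTPD(3.0, 0, 0.0).mgf(1.0) == pytest.approx(3 / 2)
        num, _ = integrate.quad(lambda x: math.exp(0.5 * x) * law.pdf(x), 0, 200, limit=200)
        assert law.mgf(0.5) == pytest.approx(num, rel=1e-7)
        with pytest.raises(ValueError):
            law.mgf(2.0)


class TestIncompleteMoments:
    def test_total_mass_limit(self):
        law = gd(0.5, 1.5)
        assert law.incomplete_moment(1, 500.0) == pytest.approx(law.raw_moment(1), abs=1e-8)

    def test_quadrature_match(self):
        law = gd(0.5, 1.5)
        num, _ = integrate.quad(lambda x: x * law.pdf(x), 0, 2.0, limit=200)
        assert law.incomplete_moment(1, 2.0) == pytest.approx(num, abs=1e-8)

    def test_memoryless_mean_residual_life(self):
        law = GTPD(2.5, 0, 0.0)
        for t in (0.1, 1.0, 5.0):
            assert law.mean_residual_life(t) == pytest.approx(1 / 2.5, abs=1e-10)

    def test_mean_waiting_time_bounds(self):
        law = gd(1.5, 2.5)
        t = 2.0
        mwt = law.mean_waiting_time(t)
        assert 0 < mwt < t

    def test_lorenz_bonferroni_limits(self):
        law = gd(0.5, 1.5)
        assert law.lorenz(0.9999) == pytest.approx(1.0, abs=1e-3)
        assert law.bonferroni(0.9999) == pytest.approx(1.0, abs=1e-3)
        p = 0.37
        assert law.bonferroni(p) == pytest.approx(law.lorenz(p) / p, rel=1e-12)
        assert law.lorenz(p) < p  # Lorenz curve below the diagonal


# ---------------------------------------------------------------------------
# quantiles and sampling
# ---------------------------------------------------------------------------


class TestQuantile:
    def test_exponential_median(self):
        assert GTPD(1, 0, 0.0).quantile(0.5) == pytest.approx(math.log(2), abs=1e-10)

    def test_round_trip(self):
        law = gd(2, 4)
        ps = np.linspace(0.01, 0.99, 25)
        qs = law.quantile(ps)
        np.testing.assert_allclose(law.cdf(qs), ps, atol=1e-9)
        assert np.all(np.diff(qs) > 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(theta=st.floats(0.2, 4.0), k=st.floats(0.0, 6.0), p=st.floats(0.01, 0.99))
    def test_round_trip_property(self, theta, k, p):
        law = gd(theta, k)
        assert law.cdf(law.quantile(p)) == pytest.approx(p, abs=1e-9)


class TestSampling:
    def test_positive_and_deterministic(self):
        law = gd(0.5, 1.5)
        a = law.rvs(1000, seed=7)
        b = law.rvs(1000, seed=7)
        assert np.all(a > 0)
        np.testing.assert_array_equal(a, b)

    def test_ks_against_analytic_cdf(self):
        law = gd(0.5, 1.5)
        n = 100_000
        x = law.rvs(n, seed=99)
        d = stats.kstest(x, law.cdf).statistic
        assert d < 1.63 / math.sqrt(n)  # 1% critical value

    def test_sample_mean_clt_bound(self):
        law = gd(0.5, 1.5)
        n = 100_000
        x = law.rvs(n, seed=5)
        mean, var = law.raw_moment(1), law.summary_measures()["variance"]
        assert abs(x.mean() - mean) < 4 * math.sqrt(var / n)


# ---------------------------------------------------------------------------
# shape classification, entropy, stochastic order
# ---------------------------------------------------------------------------


class TestShapes:
    def test_k_equal_one_mode(self):
        rep = GTPD(1.0, 1.0, 0.5).classify_shapes()
        assert rep.pdf_shape == "unimodal"
        assert rep.pdf_mode == pytest.approx(0.5)

    def test_k_below_one_unimodal_branch(self):
        rep = GTPD(1.0, 0.5, 10.0).classify_shapes()  # k - theta(b+1) = -10.5 <= 0
        assert rep.pdf_shape == "unimodal"

    def test_hazard_classification(self):
        assert gd(2.5, 0.5).classify_shapes().hrf_shape == "increasing"
        rep = gd(0.5, 1.5).classify_shapes()
        assert rep.hrf_shape == "decreasing-increasing"
        assert rep.glaser_point == pytest.approx((4.0 * 0.5) ** (1 / 1.5))
        assert rep.hrf_min_location is not None

    def test_mode_against_grid_argmax(self, rng):
        checked = 0
        while checked < 20:
            theta = float(rng.uniform(0.3, 3.0))
            k = float(rng.uniform(0.1, 5.0))
            law = gd(theta, k)
            rep = law.classify_shapes()
            if rep.pdf_mode is None or rep.pdf_mode <= 0:
                continue
            hi = law.quantile(0.999)
            grid = np.linspace(1e-9, hi, 8000)
            argmax = grid[np.argmax(law.pdf(grid))]
            if rep.pdf_shape == "decreasing-increasing-decreasing" and law.pdf(0.0) > law.pdf(rep.pdf_mode):
                continue  # boundary maximum dominates the interior bump
            assert argmax == pytest.approx(rep.pdf_mode, abs=2 * (grid[1] - grid[0]))
            checked += 1


class TestEntropy:
    def test_exponential_renyi(self):
        theta = 1.7
        law = GTPD(theta, 0, 0.0)
        # int f^2 = theta/2 -> I_R(2) = log(2/theta)
        assert law.renyi_entropy(2.0) == pytest.approx(math.log(2 / theta), rel=1e-8)

    @pytest.mark.parametrize("s", [2, 3])
    def test_series_matches_quadrature(self, s):
        law = GTPD(1.0, 1.0, 1.0)
        assert law.renyi_entropy_series(s) == pytest.approx(law.renyi_entropy(s), rel=1e-6)

    def test_limit_brackets_shannon(self):
        law = gd(0.5, 1.5)
        shannon = law.shannon_entropy()
        lo = law.renyi_entropy(1 + 1e-4)
        hi = law.renyi_entropy(1 - 1e-4)
        assert min(lo, hi) - 1e-3 <= shannon <= max(lo, hi) + 1e-3


class TestLikelihoodRatioOrder:
    def test_identical_specs(self):
        a = gd(1.0, 1.0)
        assert check_lr_order(a, a, np.linspace(0.01, 10, 100))

    def test_order_holds_equal_shape(self):
        # equal k, b1 >= b2, theta1 >= theta2: d/dt log(f1/f2) <= 0 exactly
        s1 = GTPD(2.0, 1.0, 1.0)
        s2 = GTPD(1.0, 1.0, 1.0)
        grid = np.linspace(0.01, 20, 1000)
        assert check_lr_order(s1, s2, grid)

    def test_order_holds_pure_gamma(self):
        # b = 0 reduces the ratio to t^(k1-k2) e^(-(th1-th2)t), monotone when
        # k1 <= k2 and theta1 >= theta2
        s1 = GTPD(1.5, 1.0, 0.0)
        s2 = GTPD(1.0, 2.0, 0.0)
        grid = np.linspace(0.01, 20, 1000)
        assert check_lr_order(s1, s2, grid)

    def test_order_fails_when_hypothesis_violated(self):
        s1 = GTPD(1.0, 0.5, 1.0)
        s2 = GTPD(2.0, 1.5, 1.0)
        grid = np.linspace(0.01, 20, 1000)
        assert not check_lr_order(s1, s2, grid)

    def test_unequal_shapes_with_positive_b_break_monotonicity(self):
        # with k1 < k2 and b > 0 the ratio rises near the origin (the
        # k1 t^(k1-1) b term dominates), so these conditions alone do not
        # deliver the likelihood-ratio order; the checker must detect it
        s1 = GTPD(2.0, 0.5, 1.0)
        s2 = GTPD(1.0, 1.5, 1.0)
        grid = np.linspace(1e-3, 20, 2000)
        assert not check_lr_order(s1, s2, grid)


class TestReductions:
    def test_gamma_special_case(self):
        # b = 0 reduces to gamma(k+1, theta)
        law = GTPD(1.3, 2.2, 0.0)
        ref = stats.gamma(a=3.2, scale=1 / 1.3)
        x = np.linspace(0.01, 10, 50)
        np.testing.assert_allclose(law.pdf(x), ref.pdf(x), rtol=1e-10)
        np.testing.assert_allclose(law.cdf(x), ref.cdf(x), rtol=1e-10, atol=1e-12)
        assert law.raw_moment(1) == pytest.approx(ref.mean(), rel=1e-12)

    def test_exponential_special_case(self):
        law = GTPD(0.7, 0, 0.0)
        ref = stats.expon(scale=1 / 0.7)
        x = np.linspace(0, 10, 50)
        np.testing.assert_allclose(law.pdf(x), ref.pdf(x), rtol=1e-12)
        np.testing.assert_allclose(law.cdf(x), ref.cdf(x), atol=1e-13)
        assert law.raw_moment(2) == pytest.approx(2 / 0.7 ** 2, rel=1e-12)
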