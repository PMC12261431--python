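import math

import numpy as np
import pytest
from scipy import integrate, stats

from branchfit._num import (
    bd_p0_b,
    euler_inversion_cdf,
    euler_inversion_density,
    exp_poly_integral,
    exp_poly_integral_scalar,
)
from branchfit.laws import (
    LawTree,
    Profile,
    child_profile,
    conditional_cdf,
    conditional_cumulants,
    conditional_density,
    deterministic_scale,
    finite_time_h,
    lifetime_risk_analytic,
    make_laplace_h,
    root_child_law,
    sampling_density,
    sampling_survival,
)
from branchfit.rates import tree_rates
from conftest import chain_params, chain_tree


class TestExpPolyIntegral:
    @pytest.mark.parametrize("a", [-0.7, -1e-6, 0.0, 1e-6, 0.4])
    @pytest.mark.parametrize("r", [1, 2, 4])
    def test_against_quadrature(self, a, r):
        t = 13.0
        oracle, _ = integrate.quad(lambda s: s ** (r - 1) * math.exp(a * s), 0, t)
        assert float(exp_poly_integral(t, a, r)) == pytest.approx(oracle, rel=1e-9)
        assert exp_poly_integral_scalar(t, a, r) == pytest.approx(oracle, rel=1e-9)


class TestEulerInversion:
    def test_exponential_density_recovered(self):
        m = 2.5
        lap = lambda th: 1.0 / (1.0 + m * th)
        xs = np.array([0.3, 1.0, 2.0, 5.0])
        dens = euler_inversion_density(lap, xs)
        assert np.allclose(dens, np.exp(-xs / m) / m, atol=1e-6)

    def test_gamma_cdf_recovered(self):
        shape, scale = 3.0, 1.7
        lap = lambda th: (1.0 + scale * th) ** (-shape)
        xs = np.array([1.0, 4.0, 9.0])
        cdf = euler_inversion_cdf(lap, xs)
        assert np.allclose(cdf, stats.gamma.cdf(xs, shape, scale=scale), atol=1e-7)


class TestProfiles:
    def test_convolution_matches_quadrature(self):
        g = Profile(((1.0, 0.15, 1), (0.5, -0.2, 0)))
        lam = 0.3
        conv = g.convolve_exp(lam)
        for s in (1.0, 5.0, 20.0):
            oracle, _ = integrate.quad(
                lambda x: float(g(np.array(x))) * math.exp(lam * (s - x)), 0, s)
            assert float(conv(np.array(s))) == pytest.approx(oracle, rel=1e-8)

    def test_tied_exponent_produces_secular_term(self):
        g = Profile(((2.0, 0.3, 0),))
        conv = g.convolve_exp(0.3)
        # int_0^s 2 e^{0.3x} e^{0.3(s-x)} dx = 2 s e^{0.3 s}
        assert float(conv(np.array(4.0))) == pytest.approx(8 * math.exp(1.2))

    def test_root_child_profile_is_establishment_curve(self):
        # supercritical root child: mean trajectory (e^{lam s} - 1) per C~
        profile, slope = child_profile(Profile.constant(), nu=1e-3, lam=0.2)
        s = np.array([0.0, 3.0, 10.0])
        assert np.allclose(profile(s), np.expm1(0.2 * s), rtol=1e-12)
        assert slope == pytest.approx(1e-3 / 0.2)


class TestDeterministicScale:
    @pytest.mark.parametrize("t,delta,r,expected", [
        (7.0, 0.0, 1, 1.0),
        (10.0, 0.2, 1, math.e**2),
        (10.0, 0.2, 2, 10 * math.e**2),
    ])
    def test_closed_form(self, t, delta, r, expected):
        assert float(deterministic_scale(t, delta, r)) == pytest.approx(expected)


class TestRootChildLaw:
    def test_supercritical_gamma_shape_and_mean(self):
        params = chain_params([1.0], mu=1e-4, C0=1e5)
        rates = tree_rates(chain_tree(1), params)["v1"]
        law = root_child_law(params.C0, rates, params.beta)
        assert law.kind == "gamma"
        assert law.shape == pytest.approx(1e5 * 1e-4 / 2.0)
        # mean of the limit equals C0 nu / lambda
        assert law.mean() == pytest.approx(1e5 * 1e-4 / 1.0)

    def test_deleterious_selects_negative_binomial(self):
        params = chain_params([-0.3], mu=1e-3)
        rates = tree_rates(chain_tree(1), params)["v1"]
        law = root_child_law(params.C0, rates, params.beta)
        assert law.kind == "negative_binomial"
        # stationary mean C0 nu / (beta - alpha)
        assert law.mean() == pytest.approx(params.C0 * 1e-3 / 0.3)

    def test_rescaled_mean_matches_simulation(self):
        # two-type supercritical process: empirical mean of e^{-lam t} C(t)
        from branchfit.simulate import simulate_fixed_topology

        rng = np.random.default_rng(0)
        lam, mu, C0, T = 0.25, 1e-3, 2e4, 50.0
        X, _ = simulate_fixed_topology([-1], [lam], [mu], C0, 1.0, T, 0.05,
                                       3000, rng)
        params = chain_params([lam], mu=mu, C0=C0)
        law = LawTree(chain_tree(1), params).laws["v1"]
        emp = X[:, 0] / float(law.profile(np.asarray(T)))
        se = emp.std() / math.sqrt(len(emp))
        assert abs(emp.mean() - law.mean()) < 4 * se


class TestLaplaceH:
    def setup_method(self):
        self.params = chain_params([0.1, 0.3])
        self.rates = tree_rates(chain_tree(2), self.params)

    def test_h_vanishes_at_zero_and_is_nondecreasing(self):
        lt = LawTree(chain_tree(2), self.params)
        h = lt.laws["v2"].h
        grid = np.linspace(0, 10, 40)
        vals = h(grid)
        assert vals[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(vals) >= 0)

    def test_branch_selection(self):
        fitter = make_laplace_h(self.rates["v2"], parent_delta=0.1, parent_r=1)
        assert fitter.kind == "fitter"
        less = make_laplace_h(self.rates["v1"], parent_delta=0.3, parent_r=1)
        assert less.kind == "less_fit" and less.slope == pytest.approx(
            self.rates["v1"].nu / 0.2)
        equal = make_laplace_h(self.rates["v1"], parent_delta=self.rates["v1"].lam,
                               parent_r=2)
        assert equal.kind == "equally_fit"
        assert equal.slope == pytest.approx(self.rates["v1"].nu / 2)

    def test_finite_time_h_converges_to_asymptotic(self):
        lt = LawTree(chain_tree(2), self.params)
        r2 = self.rates["v2"]
        g1 = lt.profiles["v1"]
        h_inf = lt.laws["v2"].h
        theta = np.array([0.5, 2.0, 8.0])
        for T, tol in ((40.0, 0.05), (90.0, 1e-3)):
            h_T = finite_time_h(r2, self.params.beta, T, g1,
                                child_scale=float(np.exp(r2.lam * T)))
            rel = np.abs(h_T(theta) - h_inf(theta)) / h_inf(theta)
            assert np.all(rel < tol)

    def test_cumulants_match_transform_derivatives(self):
        # d^j/dtheta^j of the finite-time exponent at 0 = cumulants
        r2 = self.rates["v2"]
        lt = LawTree(chain_tree(2), self.params)
        g1 = lt.profiles["v1"]
        T = 30.0
        scale = math.exp(r2.lam * T)
        h_T = finite_time_h(r2, self.params.beta, T, g1, child_scale=scale)
        k1, k2, k3 = conditional_cumulants(r2, g1, T, child_scale=scale)
        eps = 1e-2  # small on the rescaled-theta scale
        vals = h_T(np.array([-2 * eps, -eps, 0.0, eps, 2 * eps]))
        d1 = (vals[3] - vals[1]) / (2 * eps)
        d2 = (vals[3] - 2 * vals[2] + vals[1]) / eps**2
        d3 = (vals[4] - 2 * vals[3] + 2 * vals[1] - vals[0]) / (2 * eps**3)
        assert d1 == pytest.approx(k1, rel=1e-3)
        assert -d2 == pytest.approx(k2, rel=1e-2)
        assert d3 == pytest.approx(k3, rel=5e-2)


class TestConditionalDensity:
    def test_linear_exponent_gives_step_cdf(self):
        k, c_parent = 0.05, 40.0
        h = lambda th: k * np.asarray(th)
        step_at = k * c_parent
        below = conditional_cdf(np.array([0.5 * step_at]), c_parent, h)[0]
        above = conditional_cdf(np.array([2.0 * step_at]), c_parent, h)[0]
        assert below < 0.05 and above > 0.95

    def test_exponential_transform_pair(self):
        m, c_parent = 3.0, 2.0
        h = lambda th: np.log1p(m * np.asarray(th)) / c_parent
        xs = np.array([0.5, 2.0, 6.0])
        dens = conditional_density(xs, c_parent, h)
        assert np.allclose(dens, np.exp(-xs / m) / m, atol=1e-6)

    def test_matches_simulated_conditional_cdf(self):
        # three-type chain: child rescaled size given parent-size bin
        from branchfit.simulate import simulate_fixed_topology

        rng = np.random.default_rng(4)
        params = chain_params([0.1, 0.3], C0=1e4)
        T = 70.0
        X, _ = simulate_fixed_topology([-1, 0], [0.1, 0.3], [1e-3] * 2, 1e4,
                                       1.0, T, 0.05, 4000, rng)
        lt = LawTree(chain_tree(2), params)
        c1 = X[:, 0] / float(lt.profiles["v1"](np.asarray(T)))
        c2 = X[:, 1] / float(lt.profiles["v2"](np.asarray(T)))
        # condition on a narrow parent bin around its median
        med = np.median(c1)
        sel = (c1 > 0.9 * med) & (c1 < 1.1 * med)
        sample = np.sort(c2[sel])
        h = lt.laws["v2"].h
        grid = np.quantile(sample, np.linspace(0.05, 0.95, 19))
        cdf = conditional_cdf(grid, float(np.mean(c1[sel])), h, M=12)
        emp = np.searchsorted(sample, grid, side="right") / len(sample)
        assert np.max(np.abs(cdf - emp)) < 0.05


class TestSamplingTime:
    def test_zero_tumor_survival_is_one(self):
        surv = sampling_survival([0.0], [Profile.constant()], 10.0, 1e6,
                                 np.array([5.0, 20.0]))
        assert np.allclose(surv, 1.0)

    def test_constant_tumor_is_exponential(self):
        c, Cs = 5e4, 1e6
        surv = sampling_survival([c], [Profile.constant()], 10.0, Cs,
                                 np.array([1.0, 3.0]))
        assert np.allclose(surv, np.exp(-c / Cs * np.array([1.0, 3.0])))
        dens = sampling_density([c], [Profile.constant()], 2.0, Cs)
        assert dens == pytest.approx(c / Cs * math.exp(-c / Cs * 2.0))

    def test_exponential_subclone_closed_form(self):
        lam, Cs, ts = 0.3, 1e8, 30.0
        g = Profile(((1.0, lam, 0),))  # C(s) = C~ e^{lam s}
        size_ts = 2e5
        tilde = size_ts / math.exp(lam * ts)
        t = np.array([10.0, 25.0, 40.0])
        expected = np.exp(-tilde * (np.exp(lam * t) - 1) / (lam * Cs))
        got = sampling_survival([size_ts], [g], ts, Cs, t)
        assert np.allclose(got, expected, rtol=1e-10)
        # and against numerical quadrature of the hazard
        for ti in t:
            q, _ = integrate.quad(lambda s: tilde * math.exp(lam * s) / Cs, 0, ti)
            assert float(sampling_survival([size_ts], [g], ts, Cs, ti)) == \
                pytest.approx(math.exp(-q), rel=1e-10)

    def test_density_matches_survival_derivative(self):
        params = chain_params([0.2, 0.1])
        lt = LawTree(chain_tree(2), params)
        sizes, profiles = [3e6, 5e5], [lt.profiles["v1"], lt.profiles["v2"]]
        ts = 35.0
        dens = sampling_density(sizes, profiles, ts, params.C_sampling)
        eps = 1e-5
        s = lambda t: float(sampling_survival(sizes, profiles, ts,
                                              params.C_sampling, t))
        fd = -(s(ts + eps) - s(ts - eps)) / (2 * eps)
        assert dens == pytest.approx(fd, rel=1e-6)

    def test_marginal_ts_density_integrates_to_lifetime_risk(self):
        params = chain_params([0.3], mu=1e-3, C0=1e4, C_sampling=1e8, t_max=60.0)
        lt = LawTree(chain_tree(1), params)
        grid = np.linspace(1e-3, params.t_max, 400)
        surv = lt.ts_survival(grid)
        dens = -np.gradient(surv, grid)
        zeta = lifetime_risk_analytic(params, max_mutations=1)
        assert zeta == pytest.approx(1.0 - surv[-1], abs=1e-9)
        assert np.trapezoid(dens, grid) == pytest.approx(zeta, abs=5e-3)
        assert 0.0 < zeta < 1.0


class TestHitchhikingProportionality:
    def test_conditional_child_mean_proportional_to_parent(self):
        # less-fit child: mean of rescaled child size within parent-size bins
        # should scale linearly with the bin's parent size
        from branchfit.simulate import simulate_fixed_topology

        rng = np.random.default_rng(9)
        params = chain_params([0.3, 0.1], C0=1e4)
        T = 45.0
        X, _ = simulate_fixed_topology([-1, 0], [0.3, 0.1], [1e-3] * 2, 1e4,
                                       1.0, T, 0.05, 4000, rng)
        lt = LawTree(chain_tree(2), params)
        c1 = X[:, 0] / float(lt.profiles["v1"](np.asarray(T)))
        c2 = X[:, 1] / float(lt.profiles["v2"](np.asarray(T)))
        qs = np.quantile(c1, [0.2, 0.4, 0.6, 0.8])
        bins = np.digitize(c1, qs)
        ratios = []
        for b in range(5):
            sel = bins == b
            if sel.sum() > 100 and np.mean(c1[sel]) > 0:
                ratios.append(np.mean(c2[sel]) / np.mean(c1[sel]))
        ratios = np.array(ratios)
        assert np.all(np.abs(ratios / lt.laws["v2"].h.slope - 1.0) < 0.15)
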