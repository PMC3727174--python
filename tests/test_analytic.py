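"""Analytic cumulant densities: closed forms, conservation, count cumulants."""

import numpy as np
import pytest
from scipy import integrate, stats

import gtas
from gtas import analytic
from gtas.analytic import AnalyticDensityUnavailable
from gtas.model import validate_model
from gtas.shifts import DeltaShift, EmpiricalShift, GaussianShift, hypoexp_pdf


class TestCrossCumulantDensity:
    def test_sip_pair_is_pure_atom(self):
        m = gtas.make_sip(2.0, [3.0, 3.0])
        ax = np.linspace(-2, 2, 41)
        cd = analytic.cross_cumulant_density(m, (1, 2), [ax])
        assert np.all(cd.values == 0.0)
        assert len(cd.atoms) == 1
        vec, mass = cd.atoms[0]
        assert vec[0] == 0.0 and mass == pytest.approx(2.0)  # lambda * p_pop

    def test_cascade_pair_eq1_decomposition(self, models):
        """kappa_13 = Gaussian pair contribution + population hypoexponential
        contribution."""
        m = models["cascade_exp_n6"]
        ax = np.linspace(-4, 10, 281)
        cd = analytic.cross_cumulant_density(m, (1, 3), [ax])
        lam = m.mother_rate
        c2 = lam * m.markings[(1, 3)] * stats.norm.pdf(ax, scale=np.sqrt(2.0))
        a2, a3 = 2.0, 1.0
        cN = lam * m.markings[m.full_set] * np.where(
            ax >= 0, a2 * a3 / (a3 - a2) * (np.exp(-a2 * np.clip(ax, 0, None))
                                            - np.exp(-a3 * np.clip(ax, 0, None))), 0.0
        )
        assert cd.values == pytest.approx(c2 + cN, abs=1e-12)

    def test_exp_cumsum_full_set_at_zero_lags(self):
        """Unit rates, lambda*p_pop = 1: density at the origin is the product
        of the gap rates."""
        m = validate_model(
            3, 2.0, {(1, 2, 3): 0.5, (1,): 0.5},
            {(1, 2, 3): gtas.ExpCumsumShift(3, [1.0, 1.0, 1.0]),
             (1,): DeltaShift(3)},
        )
        cd = analytic.cross_cumulant_density(m, (1, 2, 3), [np.array([0.0]),
                                                            np.array([0.0])])
        assert cd.values[0, 0] == pytest.approx(1.0)

    def test_empirical_shift_signals_unavailable(self):
        m = validate_model(
            2, 1.0, {(1, 2): 1.0},
            {(1, 2): EmpiricalShift(2, [[0.0, 0.1], [0.0, 0.3]])},
        )
        with pytest.raises(AnalyticDensityUnavailable):
            analytic.cross_cumulant_density(m, (1, 2), [np.linspace(-1, 1, 5)])

    def test_jittered_pair_classic_convolution(self):
        """One pair marking with IID univariate jitter f on each coordinate:
        kappa_12(tau) = lambda*p*(f star f)(tau)."""
        lam, p, sig = 3.0, 0.4, 0.8
        m = validate_model(
            2, lam, {(1, 2): p, (1,): 0.6},
            {(1, 2): GaussianShift(2, cov=sig**2 * np.eye(2)), (1,): DeltaShift(2)},
        )
        ax = np.linspace(-4, 4, 81)
        cd = analytic.cross_cumulant_density(m, (1, 2), [ax])
        ref = lam * p * stats.norm.pdf(ax, scale=np.sqrt(2) * sig)
        assert cd.values == pytest.approx(ref, rel=1e-10)

    def test_same_shift_for_all_markings_reduces_to_tail(self):
        """Q_D == Q: the density is lambda * pbar_{ij} times the single-Q
        difference density."""
        q = GaussianShift(3, sigma=0.5)
        m = validate_model(
            3, 2.0, {(1, 2): 0.3, (1, 2, 3): 0.2, (3,): 0.5},
            {(1, 2): q, (1, 2, 3): q, (3,): q},
        )
        ax = np.linspace(-2, 2, 21)
        cd = analytic.cross_cumulant_density(m, (1, 2), [ax])
        pbar = gtas.tail_probability(m, (1, 2))
        ref = 2.0 * pbar * q.difference_density((1, 2), ax[:, None])
        assert cd.values == pytest.approx(ref, rel=1e-12)


class TestInfiniteWindow:
    def test_direct_value(self):
        m = validate_model(
            4, 10.0, {(1, 2, 3, 4): 0.1, (1,): 0.9},
            {(1, 2, 3, 4): DeltaShift(4), (1,): DeltaShift(4)},
        )
        assert analytic.infinite_window_cumulant(m, (1, 2, 3, 4)) == pytest.approx(1.0)

    def test_monotone_under_extension(self, models):
        m = models["cascade_exp_n6"]
        for idx in [(1,), (1, 2), (1, 2, 3), (1, 2, 3, 4), (1, 2, 3, 4, 5)]:
            assert analytic.infinite_window_cumulant(m, idx) >= \
                analytic.infinite_window_cumulant(m, idx + (6,)) - 1e-15

    def test_singleton_is_marginal_rate(self, models):
        m = models["sip_small"]
        assert analytic.infinite_window_cumulant(m, (1,)) == \
            pytest.approx(gtas.marginal_rate(m, 1))


class TestCountCumulant:
    def test_sip_pair_identical_windows(self):
        m = gtas.make_sip(2.0, [3.0, 3.0])
        T = 7.0
        val = analytic.count_cumulant(m, (1, 2), [(0.0, T), (0.0, T)])
        assert val == pytest.approx(2.0 * T)

    def test_disjoint_far_windows_zero(self):
        m = gtas.make_sip(2.0, [3.0, 3.0])
        assert analytic.count_cumulant(m, (1, 2), [(0.0, 1.0), (50.0, 51.0)]) == 0.0

    def test_repeated_index_reduction(self):
        m = gtas.make_sip(2.0, [3.0, 3.0, 3.0])
        a = analytic.count_cumulant(m, (1, 1, 3), [(0.0, 4.0), (2.0, 9.0), (0.0, 9.0)])
        b = analytic.count_cumulant(m, (1, 3), [(2.0, 4.0), (0.0, 9.0)])
        assert a == pytest.approx(b)

    def test_gaussian_pair_quadrature_vs_density_integral(self):
        lam, p, sig = 2.0, 1.0, 0.6
        m = validate_model(2, lam, {(1, 2): p},
                           {(1, 2): GaussianShift(2, cov=sig**2 * np.eye(2))})
        w = [(0.0, 3.0), (1.0, 2.5)]
        val = analytic.count_cumulant(m, (1, 2), w)
        # oracle: direct 2-D integral of the covariance density over windows
        fn = analytic.cross_cumulant_density_fn(m, (1, 2))
        ref, _ = integrate.dblquad(
            lambda s, t: float(fn(np.array([s - t]))), w[0][0], w[0][1],
            lambda t: w[1][0], lambda t: w[1][1],
        )
        assert val == pytest.approx(ref, abs=1e-6)


class TestPopulationDensity:
    def test_two_train_population_equals_pair(self):
        m = gtas.make_sip(1.0, [1.0, 1.0])
        ax = np.linspace(-1, 1, 11)
        pop = analytic.population_cumulant_density(m, (1,), [ax])
        pair = analytic.cross_cumulant_density(m, (1, 2), [ax])
        assert pop.values == pytest.approx(pair.values)
        assert pop.singular_mass == pytest.approx(pair.singular_mass)

    def test_cascade_leader_and_follower_centers_of_mass(self, models):
        m = models["cascade_exp_n6"]
        ax = np.linspace(-12, 12, 481)
        first = analytic.population_cumulant_density(m, (1,), [ax])
        last = analytic.population_cumulant_density(m, (6,), [ax])
        com_first = np.trapezoid(ax * first.values, ax) / np.trapezoid(first.values, ax)
        com_last = np.trapezoid(ax * last.values, ax) / np.trapezoid(last.values, ax)
        assert com_first > 0 and com_last < 0

    def test_third_order_support_cone(self, models):
        """kappa_{12,pop} of the cascade is confined to tau2 > tau1 > 0."""
        m = models["cascade_exp_n6"]
        ax = np.linspace(-3, 9, 61)
        pop = analytic.population_cumulant_density(m, (1, 2), [ax, ax])
        t1, t2 = np.meshgrid(ax, ax, indexing="ij")
        outside = (t1 < 0) | (t2 < t1)
        assert np.all(pop.values[outside] == 0.0)
        assert pop.values.max() > 0


class TestCascadeClosedForm:
    def test_out_of_cone_zero(self, models):
        m = models["cascade_exp_n6"]
        alphas = m.shifts[m.full_set].alphas
        taus = np.array([2.0, 1.0, 0.5, 3.0, 2.0])  # tau_2 < tau_1
        assert gtas.cascade_closed_form(alphas, 1.0, tuple(range(1, 7)), taus) == 0.0

    def test_eq6_triplet_formula(self, models):
        m = models["cascade_exp_n6"]
        alphas = m.shifts[m.full_set].alphas
        lam_pop = m.mother_rate * m.markings[m.full_set]
        a2, a3, a4 = alphas[1], alphas[2], alphas[3]
        rng = np.random.default_rng(31)
        for _ in range(20):
            t1 = rng.uniform(0, 3)
            t2 = t1 + rng.uniform(0, 3)
            ref = (lam_pop * a2 * a3 * a4 / (a4 - a3) * np.exp(-a2 * t1)
                   * (np.exp(-a3 * (t2 - t1)) - np.exp(-a4 * (t2 - t1))))
            val = gtas.cascade_closed_form(alphas, lam_pop, (1, 2, 4),
                                           np.array([t1, t2]))
            assert val == pytest.approx(ref, rel=1e-12)

    def test_equal_rate_gamma_limit(self):
        """alpha_3 = alpha_4 branch: the gap law becomes an Erlang."""
        alphas = np.array([1.0, 2.0, 1.5, 1.5])
        t1, t2 = 0.5, 1.7
        val = gtas.cascade_closed_form(alphas, 1.0, (1, 2, 4), np.array([t1, t2]))
        ref = (alphas[1] * np.exp(-alphas[1] * t1)
               * alphas[2] * alphas[3] * (t2 - t1) * np.exp(-alphas[2] * (t2 - t1)))
        assert val == pytest.approx(ref, rel=1e-12)

    def test_agreement_with_generic_density(self, models):
        """Closed form == the generic marking-sum density on the population
        contribution, over random subsets and lags."""
        m = models["cascade_exp_n6"]
        alphas = m.shifts[m.full_set].alphas
        lam_pop = m.mother_rate * m.markings[m.full_set]
        rng = np.random.default_rng(32)
        for _ in range(20):
            k = rng.integers(2, 5)
            subset = tuple(sorted(rng.choice(np.arange(1, 7), size=k, replace=False)))
            taus = np.sort(rng.uniform(0, 4, size=k - 1))
            ref = gtas.cascade_closed_form(alphas, lam_pop, subset, taus)
            dist = m.shifts[m.full_set]
            generic = lam_pop * dist.difference_density(subset, taus)
            assert abs(ref - generic) < 1e-6


class TestConservation:
    @pytest.mark.parametrize("name", ["cascade_exp_n6", "cascade_gamma_n6"])
    def test_quadrature_mass_equals_lambda_pbar(self, models, name):
        import itertools
        m = models[name]
        for k in (2, 3, 4):
            for idx in itertools.combinations(range(1, 7), k):
                mass = analytic.total_cumulant_mass(m, idx)
                assert mass == pytest.approx(
                    analytic.infinite_window_cumulant(m, idx), rel=1e-6
                )

    def test_grid_integral_close(self, models):
        m = models["cascade_exp_n6"]
        ax = np.linspace(-5, 12, 341)
        cd = analytic.cross_cumulant_density(m, (1, 3), [ax])
        assert cd.integral() == pytest.approx(
            analytic.infinite_window_cumulant(m, (1, 3)), rel=2e-2
        )


class TestBinAveragedDensity:
    def test_matches_pointwise_for_smooth_density(self):
        fn = lambda taus: stats.norm.pdf(taus[..., 0], scale=2.0)
        lags = np.array([[0], [5], [-5]])
        av = analytic.bin_averaged_density(fn, lags, dt=0.1)
        pt = fn(lags * 0.1)
        assert av == pytest.approx(pt, rel=1e-3)
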