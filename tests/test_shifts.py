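"""Shift families: sampling invariants, closed-form densities, difference
densities, hypoexponential blocks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from gtas.shifts import (
    DeltaShift,
    EmpiricalShift,
    ExpCumsumShift,
    GammaCumsumShift,
    GaussianShift,
    NoClosedDensityError,
    SingularDensityError,
    hypoexp_cdf,
    hypoexp_pdf,
    hypoexp_ppf,
    shift_from_spec,
)

RNG = np.random.default_rng(20130717)


class TestHypoexponential:
    @pytest.mark.parametrize("rates", [[1.0], [1.0, 2.0], [1.0, 1.0, 1.0],
                                       [0.5, 1.5, 2.5, 4.0], [1.0, 1.0 + 5e-10, 2.0]])
    def test_density_normalized_and_matches_convolution(self, rates):
        t = np.linspace(0, 80, 16001)
        pdf = hypoexp_pdf(t, rates)
        assert np.trapezoid(pdf, t) == pytest.approx(1.0, abs=1e-5)
        # oracle: numeric convolution of exponential densities (the discrete
        # convolution has an O(dt) artifact at the jump at t=0, so compare
        # away from the origin)
        dt = t[1] - t[0]
        conv = stats.expon.pdf(t, scale=1 / rates[0])
        for r in rates[1:]:
            conv = np.convolve(conv, stats.expon.pdf(t, scale=1 / r))[: t.size] * dt
        sel = t > 10 * dt
        assert np.abs(pdf - conv)[sel].max() < 5e-3 * max(rates)

    def test_equal_rates_is_erlang(self):
        t = np.linspace(0, 20, 200)
        assert hypoexp_pdf(t, [2.0] * 4) == pytest.approx(
            stats.gamma.pdf(t, a=4, scale=0.5), abs=1e-12
        )

    def test_cdf_and_quantile_consistent(self):
        rates = [1.0, 3.0, 0.7]
        q = hypoexp_ppf(0.99, rates)
        assert hypoexp_cdf(q, rates) == pytest.approx(0.99, abs=1e-9)

    def test_negative_support(self):
        assert hypoexp_pdf(-0.5, [1.0, 2.0]) == 0.0


class TestSampling:
    def test_delta_samples_are_offsets(self):
        d = DeltaShift(3, offsets=[0.0, 1.0, 2.0])
        assert np.all(d.sample(5, RNG) == np.array([0.0, 1.0, 2.0]))

    def test_exp_cumsum_ordered_and_mean(self):
        d = ExpCumsumShift(5, [1.0] * 5)
        y = d.sample(40_000, np.random.default_rng(1))
        assert np.all(np.diff(y, axis=1) >= 0) and np.all(y[:, 0] >= 0)
        for k in range(5):  # E[Y_k] = k for unit rates
            assert y[:, k].mean() == pytest.approx(k + 1, rel=0.02)

    def test_gamma_cumsum_ordered_and_moments(self):
        d = GammaCumsumShift(4, mu_shift=2.0, sigma_shift=0.3)
        assert d.shape == pytest.approx(2.0**2 / 0.3**2)
        assert d.scale == pytest.approx(0.3**2 / 2.0)
        y = d.sample(20_000, np.random.default_rng(2))
        assert np.all(np.diff(y, axis=1) >= 0)
        assert y[:, 3].mean() == pytest.approx(8.0, rel=0.02)
        assert y[:, 3].std() == pytest.approx(0.6, rel=0.1)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            ExpCumsumShift(2, [1.0, -1.0])
        with pytest.raises(ValueError):
            GammaCumsumShift(2, 2.0, 0.0)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 6))
    def test_samples_finite(self, seed, dim):
        rng = np.random.default_rng(seed)
        for d in (DeltaShift(dim), GaussianShift(dim, sigma=2.0),
                  ExpCumsumShift(dim, np.linspace(0.5, 2, dim)),
                  GammaCumsumShift(dim, 1.0, 0.5)):
            assert np.all(np.isfinite(d.sample(8, rng)))


class TestJointDensity:
    def test_exp_cumsum_out_of_cone_is_zero(self):
        d = ExpCumsumShift(2, [1.0, 1.0])
        assert d.marginal_density((1, 2), np.array([2.0, 1.0])) == 0.0

    def test_exp_cumsum_full_joint_at_origin(self):
        d = ExpCumsumShift(2, [1.0, 1.0])
        assert d.marginal_density((1, 2), np.array([0.0, 0.0])) == pytest.approx(1.0)

    def test_exp_cumsum_full_joint_matches_conditional_factorization(self):
        alphas = [1.0, 2.0, 0.5]
        d = ExpCumsumShift(3, alphas)
        rng = np.random.default_rng(3)
        for _ in range(5):
            y = np.sort(rng.uniform(0, 3, 3))
            ref = alphas[0] * np.exp(-alphas[0] * y[0])
            for i in (1, 2):
                ref *= alphas[i] * np.exp(-alphas[i] * (y[i] - y[i - 1]))
            assert d.marginal_density((1, 2, 3), y) == pytest.approx(ref, rel=1e-12)

    def test_gaussian_matches_multivariate_normal(self):
        mean = np.array([0.5, -1.0, 2.0])
        cov = np.array([[2.0, 0.3, 0.0], [0.3, 1.0, 0.2], [0.0, 0.2, 0.5]])
        d = GaussianShift(3, mean=mean, cov=cov)
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 3))
        ref = stats.multivariate_normal(mean, cov).pdf(pts)
        assert d.marginal_density((1, 2, 3), pts) == pytest.approx(ref, rel=1e-12)

    def test_exp_cumsum_marginal_is_hypoexponential(self):
        d = ExpCumsumShift(4, [1.0, 2.0, 3.0, 4.0])
        x = np.linspace(0, 10, 50)
        assert d.marginal_density((3,), x[:, None]) == pytest.approx(
            hypoexp_pdf(x, [1.0, 2.0, 3.0]), rel=1e-10
        )

    def test_empirical_has_no_density(self):
        d = EmpiricalShift(2, [[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(NoClosedDensityError):
            d.marginal_density((1, 2), np.zeros(2))


class TestDifferenceDensity:
    def test_delta_is_symbolic(self):
        d = DeltaShift(3, offsets=[0.0, 2.0, 5.0])
        with pytest.raises(SingularDensityError):
            d.difference_density((1, 2, 3), np.zeros(2))
        atoms = d.difference_atoms((1, 2, 3))
        assert len(atoms) == 1
        vec, mass = atoms[0]
        assert np.all(vec == [2.0, 5.0]) and mass == 1.0

    def test_exp_cumsum_full_set_product_form(self):
        alpha = 1.5
        d = ExpCumsumShift(3, [alpha] * 3)
        taus = np.array([0.4, 1.0])
        ref = alpha * np.exp(-alpha * 0.4) * alpha * np.exp(-alpha * 0.6)
        assert d.difference_density((1, 2, 3), taus) == pytest.approx(ref, rel=1e-12)
        # out of the ordered cone
        assert d.difference_density((1, 2, 3), np.array([1.0, 0.4])) == 0.0

    def test_exp_cumsum_skip_subset_hypoexponential(self):
        # coordinates (1, 3): gap spans rates alpha_2, alpha_3
        a2, a3 = 2.0, 1.0
        d = ExpCumsumShift(3, [5.0, a2, a3])
        tau = np.linspace(0.01, 8, 100)[:, None]
        ref = a2 * a3 / (a3 - a2) * (np.exp(-a2 * tau[:, 0]) - np.exp(-a3 * tau[:, 0]))
        assert d.difference_density((1, 3), tau) == pytest.approx(ref, rel=1e-10)

    @pytest.mark.parametrize(
        "dist,coords",
        [
            (GaussianShift(3, sigma=1.2), (1, 3)),
            (ExpCumsumShift(4, [1.0, 2.0, 1.0, 0.5]), (1, 2, 4)),
            (GammaCumsumShift(3, 1.5, 0.8), (1, 3)),
        ],
    )
    def test_difference_density_integrates_to_one(self, dist, coords):
        k = len(coords)
        if k == 2:
            val, _ = integrate.quad(
                lambda t: float(dist.difference_density(coords, np.array([t]))),
                -50, 50, points=[0.0], limit=300,
            )
            assert val == pytest.approx(1.0, abs=1e-6)
        else:
            # midpoint rule with cell edges on the cone boundary at zero,
            # where cascade difference densities jump
            h = 0.025
            g = np.arange(-5, 40, h) + h / 2
            mesh = np.stack(np.meshgrid(g, g, indexing="ij"), axis=-1)
            vals = dist.difference_density(coords, mesh)
            assert float(vals.sum() * h * h) == pytest.approx(1.0, abs=2e-3)

    def test_monte_carlo_histogram_matches_density(self):
        d = ExpCumsumShift(3, [1.0, 2.0, 1.0])
        n = 10**6
        y = d.sample(n, np.random.default_rng(5))
        z = y[:, 2] - y[:, 0]
        edges = np.linspace(0, 6, 25)
        hist, _ = np.histogram(z, bins=edges)
        width = edges[1] - edges[0]
        # bin probabilities by fine-grid quadrature of the density (the
        # density is curved, so bin centers are not bin averages)
        fine = np.linspace(edges[0], edges[-1], 24 * 64 + 1)
        dens = d.difference_density((1, 3), fine[:, None])
        p = np.trapezoid(dens.reshape(-1), fine)  # sanity: ~1 over the range
        assert p == pytest.approx(1.0, abs=0.01)
        probs = np.array([
            np.trapezoid(dens[i * 64 : i * 64 + 65], fine[i * 64 : i * 64 + 65])
            for i in range(24)
        ])
        se = np.sqrt(np.maximum(probs * (1 - probs), 1e-12) * n)
        assert np.all(np.abs(hist - n * probs) < 3 * se + 3)

    def test_unordered_coordinate_request_consistent(self):
        d = ExpCumsumShift(3, [1.0, 2.0, 3.0])
        tau = np.array([0.7, 0.2])  # lags of trains 3 and 2 relative to 1
        a = d.difference_density((1, 3, 2), tau)
        b = d.difference_density((1, 2, 3), np.array([0.2, 0.7]))
        assert a == pytest.approx(b, rel=1e-12)


class TestBoundsAndSerialization:
    def test_exp_cumsum_bound_is_gamma_quantile(self):
        d = ExpCumsumShift(6, [1.0] * 6)
        assert d.abs_bound(1e-9) == pytest.approx(
            stats.gamma.ppf(1 - 1e-9, a=6, scale=1.0), rel=1e-8
        )

    def test_delta_bound(self):
        assert DeltaShift(2, offsets=[-3.0, 1.0]).abs_bound(1e-9) == 3.0

    @pytest.mark.parametrize(
        "dist",
        [
            DeltaShift(2, offsets=[0.0, 1.5]),
            GaussianShift(2, mean=[0.0, 1.0], cov=[[1.0, 0.2], [0.2, 2.0]]),
            ExpCumsumShift(3, [1.0, 2.0, 3.0]),
            GammaCumsumShift(2, 2.0, 0.3),
            EmpiricalShift(2, [[0.0, 1.0], [2.0, 3.0]]),
        ],
    )
    def test_spec_roundtrip(self, dist):
        again = shift_from_spec(dist.to_spec(), dist.dim)
        assert again == dist
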