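"""Tests for the action potential distribution: Lambert-W utilities,
normalization, density/CDF consistency, sampling and maximum likelihood."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import lambertw as scipy_lambertw
from scipy.stats import kstest

from suddency import (
    APDParams,
    ActionPotentialDistribution,
    DomainError,
    MembraneVoltageParams,
    OMEGA,
    fit_apd_mle,
    lambert_w0,
    membrane_voltage,
    normalization_constants,
    pointwise_inverse_series,
    rescale_for_apd,
    signal_to_smoments,
)


class TestLambertW:
    @pytest.mark.parametrize("z, w", [(0.0, 0.0), (1.0, 0.5671432904097838), (math.e, 1.0)])
    def test_known_values(self, z, w):
        assert lambert_w0(z) == pytest.approx(w, abs=1e-12)

    def test_omega_constant_four_decimals(self):
        assert round(OMEGA, 4) == 0.5671

    def test_residual_and_scipy_cross_check(self):
        assert lambert_w0(-1 / math.e) == pytest.approx(-1.0, abs=1e-6)
        for z in [-0.3, -0.05, 0.5, 2.0, 10.0, 1e4]:
            w = lambert_w0(z)
            assert abs(w * math.exp(w) - z) < 1e-12 * max(1.0, abs(z))
            assert w == pytest.approx(float(scipy_lambertw(z).real), abs=1e-10)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            lambert_w0(-0.5)


class TestMembraneVoltage:
    def test_left_branch_limit(self):
        c = 2.0
        v = membrane_voltage(1e-12, MembraneVoltageParams(c))
        assert v == pytest.approx(-1.0 - 1.0 / (c * math.e), abs=1e-5)

    def test_middle_branch_at_one(self):
        v = membrane_voltage(1.0, MembraneVoltageParams(1.0))
        assert v == pytest.approx(math.e - 1.0 / math.e, abs=1e-12)
        assert v == pytest.approx(2.3504, abs=1e-4)

    def test_right_branch_decays_to_minus_inv_e(self):
        v = membrane_voltage(50.0, MembraneVoltageParams(1.0))
        assert v == pytest.approx(-1.0 / math.e, abs=1e-12)

    @pytest.mark.parametrize("t", [1 / math.e, (math.e + 1) / math.e])
    def test_breakpoints_are_undefined(self, t):
        with pytest.raises(DomainError):
            membrane_voltage(t, MembraneVoltageParams(1.0))


class TestNormalization:
    @pytest.mark.parametrize("alpha, beta", [(1.0, 0.01), (0.5, 1.0), (0.3, 2.0)])
    def test_definitional_identities(self, alpha, beta):
        p = APDParams(alpha, beta)
        C, A, B = normalization_constants(p)
        ab = alpha * beta
        w = lambert_w0(ab)
        D = math.exp(w / (alpha**2 * beta) + beta * math.exp(w / ab))
        assert C * (D - math.exp(beta)) == pytest.approx(1.0, abs=1e-12)
        assert C == B
        # the distribution-function limits: F(-inf) = A + B e^beta = 0 and
        # F(+inf) = A + B * D = 1
        assert A + B * math.exp(beta) == pytest.approx(0.0, abs=1e-12)
        assert A + B * D == pytest.approx(1.0, abs=1e-12)

    def test_printed_positive_sign_violates_the_limits(self):
        # regression: with A taken positive the lower limit of F becomes
        # 2 e^beta / (D - e^beta) instead of 0
        p = APDParams(0.5, 1.0)
        _, A, B = normalization_constants(p)
        A_printed = -A
        lower_limit = A_printed + B * math.exp(p.beta)
        assert lower_limit == pytest.approx(2 * math.exp(p.beta) * B, abs=1e-12)
        assert lower_limit > 0.1  # nowhere near the required 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            APDParams(0.0, 1.0)
        with pytest.raises(ValueError):
            APDParams(1.2, 1.0)
        with pytest.raises(ValueError):
            APDParams(0.5, -1.0)
        with pytest.raises(DomainError):
            normalization_constants(APDParams(1.0, 800.0))


class TestRescale:
    def test_boundary_conditions(self, rng):
        p = APDParams(0.7, 1.5)
        x = rng.uniform(-3, 3, size=30)
        x[0], x[1] = -3.0, 3.0
        r = rescale_for_apd(x - x.min() + 1.0, p)
        ab = p.alpha * p.beta
        assert r.values.min() == pytest.approx(1.0, abs=1e-12)  # exp(W0(0)) = 1
        assert r.values.max() == pytest.approx(math.exp(lambert_w0(ab) / ab), abs=1e-12)
        assert 1.0 < r.values.max() < math.e

    def test_unit_params_max_is_exp_omega(self, two_level):
        r = rescale_for_apd(two_level, APDParams(1.0, 1.0))
        assert r.values.max() == pytest.approx(math.exp(OMEGA), abs=1e-10)
        assert r.values.max() == pytest.approx(1.7632, abs=1e-4)

    def test_preserves_ordering(self, rng):
        x = rng.uniform(1, 5, size=20)
        r = rescale_for_apd(x, APDParams(0.5, 1.0))
        assert np.all(np.argsort(x) == np.argsort(r.values))

    def test_constant_rejected(self):
        with pytest.raises(DomainError):
            rescale_for_apd([2.0, 2.0], APDParams(0.5, 1.0))


class TestDensity:
    def test_normalizes_to_one(self, apd_dist):
        val, _ = quad(lambda s: float(apd_dist.pdf(s)[0]), -50, 50, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_cdf_limits_and_monotone(self, apd_dist):
        assert apd_dist.cdf(-1e4)[0] == pytest.approx(0.0, abs=1e-9)
        assert apd_dist.cdf(1e4)[0] == pytest.approx(1.0, abs=1e-9)
        grid = np.linspace(-40, 40, 1000)
        F = apd_dist.cdf(grid)
        assert np.all(np.diff(F) >= 0)
        assert np.all((F >= 0) & (F <= 1))

    def test_pdf_is_cdf_derivative(self, apd_dist):
        grid = np.linspace(-8, 8, 50)
        h = 1e-5
        fd = (apd_dist.cdf(grid + h) - apd_dist.cdf(grid - h)) / (2 * h)
        f = apd_dist.pdf(grid)
        np.testing.assert_allclose(f, fd, rtol=1e-5, atol=1e-12)

    def test_pdf_continuous_in_parameters(self, two_level):
        grid = np.linspace(-10, 10, 101)
        base = ActionPotentialDistribution(two_level, APDParams(0.5, 1.0)).pdf(grid)
        pert = ActionPotentialDistribution(two_level, APDParams(0.5 + 1e-4, 1.0 + 1e-4)).pdf(grid)
        assert np.max(np.abs(base - pert)) < 1e-2


class TestSampling:
    def test_seed_reproducibility(self, apd_dist):
        a = apd_dist.sample(100, seed=7)
        b = apd_dist.sample(100, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_ks_agreement(self, apd_dist):
        smp = apd_dist.sample(10_000, seed=3)
        stat = kstest(smp, lambda q: apd_dist.cdf(q)).statistic
        assert stat < 0.02

    def test_median_sample_near_half(self, apd_dist):
        smp = apd_dist.sample(100_000, seed=5)
        assert float(apd_dist.cdf(np.median(smp))[0]) == pytest.approx(0.5, abs=0.02)

    def test_mean_matches_quadrature(self, apd_dist):
        mean_quad, _ = quad(lambda s: s * float(apd_dist.pdf(s)[0]), -50, 50, limit=200)
        smp = apd_dist.sample(20_000, seed=11)
        se = smp.std(ddof=1) / np.sqrt(smp.size)
        assert abs(smp.mean() - mean_quad) < 3 * se


class TestMLE:
    def test_single_seed_recovery(self, two_level):
        true = APDParams(0.6, 2.0)
        obs = ActionPotentialDistribution(two_level, true).sample(5000, seed=0)
        fit = fit_apd_mle(obs, two_level, seed=0)
        assert fit.params.alpha == pytest.approx(0.6, abs=0.05)
        assert fit.params.beta == pytest.approx(2.0, abs=0.2)

    def test_loglik_beats_initial_point(self, two_level):
        true = APDParams(0.6, 2.0)
        obs = ActionPotentialDistribution(two_level, true).sample(2000, seed=1)
        init = APDParams(0.5, 1.0)
        fit = fit_apd_mle(obs, two_level, init=init, seed=1)
        ll_init = float(
            ActionPotentialDistribution(two_level, init).logpdf(obs).sum()
        )
        assert fit.loglik >= ll_init

    def test_too_few_observations(self, two_level):
        with pytest.raises(ValueError):
            fit_apd_mle([0.1] * 5, two_level)

    def test_bias_shrinks_with_n(self, two_level):
        true = APDParams(0.6, 2.0)
        errs = []
        for n in (500, 5000):
            dist = ActionPotentialDistribution(two_level, true)
            e = []
            for seed in range(3):
                obs = dist.sample(n, seed=seed)
                fit = fit_apd_mle(obs, two_level, seed=seed)
                e.append(abs(fit.params.beta - true.beta))
            errs.append(np.mean(e))
        assert errs[1] <= errs[0] + 0.02


class TestSmoments:
    def test_delegates_to_pointwise_inverse(self, rng):
        x = rng.uniform(1, 2, size=30)
        np.testing.assert_array_equal(
            signal_to_smoments(x, clip=20.0), pointwise_inverse_series(x, clip=20.0)
        )
        assert signal_to_smoments(x).size == x.size

    def test_end_to_end_recovery_from_generated_signal(self, two_level):
        # draws from the APD on a fixture signal, inverted and refitted
        true = APDParams(0.6, 2.0)
        dist = ActionPotentialDistribution(two_level, true)
        obs = dist.sample(4000, seed=2)
        fit = fit_apd_mle(obs, two_level, seed=2)
        assert fit.params.alpha == pytest.approx(0.6, abs=0.05)
        assert fit.params.beta == pytest.approx(2.0, abs=0.2)
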