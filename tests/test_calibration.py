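import numpy as np
import pytest
from scipy.stats import norm

from lsmatch import (
    EffectEstimate,
    SystematicErrorModel,
    calibrate_estimate,
    ese_credible_interval,
    expected_systematic_error,
    fit_null_mle,
    sample_posterior,
)


def _estimates(theta, tau):
    return [
        EffectEstimate(f"nc_{i}", float(t), float(s), 10)
        for i, (t, s) in enumerate(zip(theta, tau))
    ]


def _simulate_controls(rng, n, mu, sigma, tau_range=(0.05, 0.3)):
    tau = rng.uniform(*tau_range, n)
    beta = rng.normal(mu, sigma, n)
    theta_hat = rng.normal(beta, tau)
    return _estimates(theta_hat, tau)


def _grid_mle(theta, tau):
    """Dense grid-search maximizer of the marginal normal likelihood."""
    mus = np.linspace(theta.min() - 0.5, theta.max() + 0.5, 400)
    sigmas = np.linspace(0, 1.5, 400)
    best, arg = -np.inf, None
    for mu in mus:
        var = sigmas[:, None] ** 2 + tau[None, :] ** 2
        ll = -0.5 * (np.log(2 * np.pi * var) + (theta - mu) ** 2 / var).sum(axis=1)
        j = np.argmax(ll)
        if ll[j] > best:
            best, arg = ll[j], (mu, sigmas[j])
    return arg


class TestMLE:
    def test_symmetric_estimates_center_at_zero(self):
        ests = _estimates([-0.4, -0.2, 0.2, 0.4], [0.1] * 4)
        model = fit_null_mle(ests)
        assert model.mu == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_500_controls(self):
        rng = np.random.default_rng(42)
        ests = _simulate_controls(rng, 500, mu=0.1, sigma=0.2)
        model = fit_null_mle(ests)
        assert model.mu == pytest.approx(0.1, rel=0.10, abs=0.02)
        assert model.sigma == pytest.approx(0.2, rel=0.10)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        ests = _simulate_controls(rng, 20, mu=0.15, sigma=0.25)
        model = fit_null_mle(ests)
        theta = np.array([e.log_hr for e in ests])
        tau = np.array([e.se for e in ests])
        mu_g, sigma_g = _grid_mle(theta, tau)
        assert model.mu == pytest.approx(mu_g, abs=0.01)
        assert model.sigma == pytest.approx(sigma_g, abs=0.01)

    def test_recovery_improves_with_more_controls(self):
        rng = np.random.default_rng(3)
        errs = []
        for n in (20, 100, 500):
            rel = []
            for _ in range(10):
                ests = _simulate_controls(rng, n, mu=0.1, sigma=0.2)
                m = fit_null_mle(ests)
                rel.append(abs(m.sigma - 0.2) / 0.2 + abs(m.mu - 0.1) / 0.1)
            errs.append(np.mean(rel))
        assert errs[2] < errs[0]

    def test_requires_two_estimable(self):
        with pytest.raises(ValueError):
            fit_null_mle([EffectEstimate("a", 0.1, 0.1, 5)])
        bad = EffectEstimate("b", np.nan, np.nan, 0, estimable=False)
        with pytest.raises(ValueError):
            fit_null_mle([EffectEstimate("a", 0.1, 0.1, 5), bad])


class TestESE:
    def test_degenerate_cases(self):
        assert expected_systematic_error(SystematicErrorModel(0.0, 0.0)) == 0.0
        assert expected_systematic_error(
            SystematicErrorModel(0.3, 0.0)
        ) == pytest.approx(0.3)
        assert expected_systematic_error(
            SystematicErrorModel(0.3, 1e-4)
        ) == pytest.approx(0.3, abs=1e-3)

    def test_standard_normal_case_vs_monte_carlo(self):
        ese = expected_systematic_error(SystematicErrorModel(0.0, 1.0))
        assert ese == pytest.approx(np.sqrt(2 / np.pi), abs=1e-12)
        rng = np.random.default_rng(0)
        mc = np.abs(rng.normal(0, 1, 10**6)).mean()
        assert ese == pytest.approx(mc, abs=3 * 1e-3)

    def test_closed_form_matches_monte_carlo_grid(self):
        rng = np.random.default_rng(1)
        n = 200_000
        for mu in (-0.5, 0.0, 0.1, 0.8):
            for sigma in (0.05, 0.2, 1.0):
                draws = np.abs(rng.normal(mu, sigma, n))
                mc_se = draws.std() / np.sqrt(n)
                ese = expected_systematic_error(SystematicErrorModel(mu, sigma))
                assert abs(ese - draws.mean()) < 3 * mc_se

    def test_monotone_in_sigma_and_abs_mu(self):
        sigmas = np.linspace(0, 1, 11)
        vals = [
            expected_systematic_error(SystematicErrorModel(0.2, s)) for s in sigmas
        ]
        assert np.all(np.diff(vals) >= 0)
        mus = np.linspace(0, 1, 11)
        vals = [
            expected_systematic_error(SystematicErrorModel(m, 0.3)) for m in mus
        ]
        assert np.all(np.diff(vals) >= 0)


class TestMCMC:
    def test_seeded_chain_reproducible(self):
        rng = np.random.default_rng(5)
        ests = _simulate_controls(rng, 30, mu=0.1, sigma=0.15)
        r1 = ese_credible_interval(ests, iterations=2000, burn_in=500, seed=9)
        r2 = ese_credible_interval(ests, iterations=2000, burn_in=500, seed=9)
        assert (r1.point, r1.ci_low, r1.ci_high) == (r2.point, r2.ci_low, r2.ci_high)

    def test_interval_shrinks_with_tight_data(self):
        rng = np.random.default_rng(6)
        loose = ese_credible_interval(
            _simulate_controls(rng, 15, 0.1, 0.2, (0.2, 0.4)),
            iterations=4000, burn_in=1000, seed=0,
        )
        tight = ese_credible_interval(
            _simulate_controls(rng, 400, 0.1, 0.2, (0.01, 0.05)),
            iterations=4000, burn_in=1000, seed=0,
        )
        assert (tight.ci_high - tight.ci_low) < (loose.ci_high - loose.ci_low)

    def test_posterior_mode_consistent_with_mle(self):
        rng = np.random.default_rng(8)
        ests = _simulate_controls(rng, 200, mu=0.2, sigma=0.25, tau_range=(0.02, 0.1))
        model = sample_posterior(ests, iterations=6000, burn_in=1500, seed=2)
        mu_post = np.median(model.posterior_samples[:, 0])
        sigma_post = np.median(model.posterior_samples[:, 1])
        assert mu_post == pytest.approx(model.mu, abs=0.03)
        assert sigma_post == pytest.approx(model.sigma, abs=0.05)

    def test_interval_matches_posterior_quadrature(self):
        """Fine-grid quadrature over (mu, log sigma) reproduces the CrI."""
        rng = np.random.default_rng(11)
        ests = _simulate_controls(rng, 20, mu=0.1, sigma=0.2)
        res = ese_credible_interval(ests, iterations=20_000, burn_in=4000, seed=3)
        theta = np.array([e.log_hr for e in ests])
        tau = np.array([e.se for e in ests])
        mus = np.linspace(theta.min() - 1, theta.max() + 1, 300)
        log_sigmas = np.linspace(-7, 1.5, 300)
        MU, LS = np.meshgrid(mus, log_sigmas, indexing="ij")
        var = np.exp(LS)[..., None] ** 2 + tau**2
        ll = -0.5 * (
            np.log(2 * np.pi * var) + (theta - MU[..., None]) ** 2 / var
        ).sum(-1)
        w = np.exp(ll - ll.max()).ravel()
        sig = np.exp(LS).ravel()
        mu_flat = MU.ravel()
        ese = sig * np.sqrt(2 / np.pi) * np.exp(
            -(mu_flat**2) / (2 * sig**2)
        ) + mu_flat * (1 - 2 * norm.cdf(-mu_flat / sig))
        order = np.argsort(ese)
        cdf = np.cumsum(w[order]) / w.sum()
        lo = ese[order][np.searchsorted(cdf, 0.025)]
        hi = ese[order][np.searchsorted(cdf, 0.975)]
        assert res.ci_low == pytest.approx(lo, abs=0.02)
        assert res.ci_high == pytest.approx(hi, abs=0.03)


class TestCalibration:
    def test_degenerate_null_is_identity(self):
        est = EffectEstimate("safety", 0.5, 0.2, 40)
        cal = calibrate_estimate(SystematicErrorModel(0.0, 0.0), est)
        assert cal.log_hr == est.log_hr
        assert cal.se == est.se
        z = abs(est.log_hr) / est.se
        assert cal.p_value == pytest.approx(2 * norm.sf(z))

    def test_p_is_one_at_null_center(self):
        est = EffectEstimate("safety", 0.3, 0.1, 40)
        cal = calibrate_estimate(SystematicErrorModel(0.3, 0.2), est)
        assert cal.p_value == pytest.approx(1.0)

    def test_calibrated_type_one_error_restored(self):
        """With injected bias, calibrated p<0.05 near 5%; uncalibrated far above."""
        rng = np.random.default_rng(13)
        mu_true, sigma_true = 0.15, 0.15
        train = _simulate_controls(rng, 100, mu_true, sigma_true)
        null = fit_null_mle(train)
        n_out = 1000
        tau = rng.uniform(0.05, 0.3, n_out)
        theta_hat = rng.normal(rng.normal(mu_true, sigma_true, n_out), tau)
        uncal_p = 2 * norm.sf(np.abs(theta_hat) / tau)
        cal_p = np.array(
            [
                calibrate_estimate(
                    null, EffectEstimate("o", t, s, 10)
                ).p_value
                for t, s in zip(theta_hat, tau)
            ]
        )
        assert (uncal_p < 0.05).mean() > 0.25
        assert (cal_p < 0.05).mean() == pytest.approx(0.05, abs=0.03)

    def test_non_estimable_rejected(self):
        bad = EffectEstimate("o", np.nan, np.nan, 0, estimable=False)
        with pytest.raises(ValueError):
            calibrate_estimate(SystematicErrorModel(0.0, 0.1), bad)
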