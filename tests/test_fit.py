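"""Likelihood, score, MLE, EM, information, Wald/LR and censoring."""

import numpy as np
import pytest
from scipy import integrate, stats

from elgdist import (
    CensoredSample,
    ELGParams,
    FitResult,
    censored_loglik,
    elg_cdf,
    elg_loglik,
    elg_pdf,
    elg_rvs,
    elg_score,
    fit_em,
    fit_mle,
    fit_mle_censored,
    lr_test,
    observed_information,
    wald_intervals,
)
from elgdist.fit import _em_z
from conftest import TABLE2_ELG


def _naive_logpdf(x, a, t, p):
    """Direct transcription of the density, used as a slow oracle."""
    g = 1.0 - (t + 1.0 + t * x) / (t + 1.0) * np.exp(-t * x)
    num = a * t**2 * (1.0 - p) * (1.0 + x) * np.exp(-t * x) * g ** (a - 1.0)
    den = (t + 1.0) * (1.0 - p + p * g**a) ** 2
    return np.log(num / den)


class TestLoglik:
    def test_published_value(self, data1):
        # Table 2: AIC = 824.6214, k = 3  =>  l = (6 - 824.6214)/2 = -409.3107
        assert elg_loglik(data1, TABLE2_ELG) == pytest.approx(-409.3107, abs=5e-4)

    def test_single_point_lindley(self):
        # x=1, alpha=1, p=0, theta=1: log[ 2^2? ] -> log(2 e^{-1} / 2) = -1
        assert elg_loglik([1.0], ELGParams(1.0, 1.0, 0.0)) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        x = rng.uniform(0.1, 10.0, size=50)
        for a, t, p in [(2.0, 1.0, 0.5), (0.7, 0.3, -0.8), (1.3, 2.2, 0.9)]:
            assert elg_loglik(x, ELGParams(a, t, p)) == pytest.approx(
                float(np.sum(_naive_logpdf(x, a, t, p))), rel=1e-10
            )

    def test_invalid_params_sentinel(self, data2):
        assert elg_loglik(data2, (-1.0, 1.0, 0.5)) == -np.inf
        assert elg_loglik(data2, (1.0, 1.0, 1.5)) == -np.inf


class TestScore:
    def test_finite_differences(self, data2):
        params = ELGParams(2.0, 1.0, 0.5)
        s = elg_score(data2, params)
        h = 1e-6
        v0 = np.array(params.as_tuple())
        for i in range(3):
            vp, vm = v0.copy(), v0.copy()
            vp[i] += h
            vm[i] -= h
            fd = (elg_loglik(data2, tuple(vp)) - elg_loglik(data2, tuple(vm))) / (2 * h)
            assert s[i] == pytest.approx(fd, rel=1e-5)

    def test_zero_at_mle(self, data1, fit1):
        s = elg_score(data1, fit1.params_hat)
        assert np.max(np.abs(s)) < 1e-3

    def test_p_component_at_zero(self, data2):
        # at p=0 the p-derivative is -n + 2*sum(1 - tau_i^alpha)
        a, t = 1.5, 0.2
        x = data2.times
        tau = 1.0 - (t + 1.0 + t * x) / (t + 1.0) * np.exp(-t * x)
        expect = -x.size + 2.0 * np.sum(1.0 - tau**a)
        s = elg_score(data2, ELGParams(a, t, 0.0))
        assert s[2] == pytest.approx(expect, rel=1e-12)


class TestFitMle:
    def test_data1_table2(self, fit1):
        a, t, p = fit1.params_hat.as_tuple()
        assert a == pytest.approx(1.0792, abs=0.005)
        assert t == pytest.approx(0.0699, abs=0.005)
        assert p == pytest.approx(0.9204, abs=0.005)

    def test_data2_table5(self, fit2):
        a, t, p = fit2.params_hat.as_tuple()
        assert a == pytest.approx(1.4602, abs=0.005)
        assert t == pytest.approx(0.1725, abs=0.005)
        assert p == pytest.approx(0.5385, abs=0.005)

    def test_parameter_recovery(self):
        truth = ELGParams(2.0, 1.0, 0.5)
        data = elg_rvs(5000, truth, seed=7)
        fit = fit_mle(data, init=truth)
        est = np.array(fit.params_hat.as_tuple())
        assert np.all(np.abs(est - np.array(truth.as_tuple())) < 3.0 * fit.se)

    def test_loglik_beats_start(self, data2, fit2):
        assert fit2.loglik >= elg_loglik(data2, ELGParams(1.0, 2.0 / np.mean(data2.times), 0.5))


class TestFitEm:
    def test_data1_matches_direct(self, data1, fit1):
        em = fit_em(data1)
        diff = np.abs(np.array(em.params_hat.as_tuple()) - np.array(fit1.params_hat.as_tuple()))
        assert np.all(diff < 1e-3)
        assert em.method == "em"

    def test_z_at_p_zero_is_one(self, data2):
        z = _em_z(data2.times, 1.5, 0.2, 0.0)
        np.testing.assert_allclose(z, 1.0, rtol=0)
        # M-step p-update: p = 1 - n/sum(z) = 0 at the no-compounding fixed point
        assert 1.0 - data2.n / float(np.sum(z)) == 0.0

    def test_rejects_nonpositive_p(self, data2):
        with pytest.raises(ValueError):
            fit_em(data2, init=ELGParams(1.0, 0.2, 0.0))
        with pytest.raises(ValueError):
            fit_em(data2, init=ELGParams(1.0, 0.2, -0.5))

    def test_ascent_on_data2(self, data2, fit2):
        # the ascent property is asserted inside fit_em at every iteration
        em = fit_em(data2, init=ELGParams(1.0, 0.1, 0.3))
        assert em.converged
        assert em.loglik == pytest.approx(fit2.loglik, abs=1e-6)


class TestObservedInformation:
    def test_finite_difference_hessian(self, data1, fit1):
        info = observed_information(data1, fit1.params_hat)
        v0 = np.array(fit1.params_hat.as_tuple())
        h = np.maximum(np.abs(v0), 1e-2) * 1e-4
        fd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                acc = 0.0
                for si, sj, sgn in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
                    v = v0.copy()
                    v[i] += si * h[i]
                    v[j] += sj * h[j]
                    acc += sgn * elg_loglik(data1, tuple(v))
                fd[i, j] = acc / (4.0 * h[i] * h[j])
        np.testing.assert_allclose(info, -fd, rtol=1e-3)

    def test_symmetry(self, data2):
        info = observed_information(data2, ELGParams(2.0, 1.0, 0.5))
        np.testing.assert_allclose(info, info.T, rtol=1e-12)

    def test_alpha_p_cross_entry_closed_form(self):
        # derived d^2 l / d alpha d p = -2 sum tau^a log(tau) / (1-p+p tau^a)^2;
        # at alpha=1, p=0 the info entry is +2 sum tau log tau
        x = np.array([0.5, 1.0, 2.0])
        t = 1.0
        tau = 1.0 - (t + 1.0 + t * x) / (t + 1.0) * np.exp(-t * x)
        info = observed_information(x, ELGParams(1.0, 1.0, 0.0))
        assert info[0, 2] == pytest.approx(2.0 * np.sum(tau * np.log(tau)), rel=1e-10)


class TestWald:
    def test_multiplier(self, fit1):
        ci = wald_intervals(fit1, level=0.95)
        a = fit1.params_hat.alpha
        half = (ci["alpha"][1] - ci["alpha"][0]) / 2.0
        assert half / fit1.se[0] == pytest.approx(1.959964, abs=1e-5)

    def test_zero_se_degenerate(self, fit1):
        degenerate = FitResult(
            params_hat=fit1.params_hat, loglik=fit1.loglik, vcov=np.zeros((3, 3)),
            se=np.zeros(3), n_iter=1, converged=True, method="direct",
        )
        ci = wald_intervals(degenerate, 0.95)
        assert ci["theta"][0] == ci["theta"][1] == fit1.params_hat.theta

    def test_level_domain(self, fit1):
        with pytest.raises(ValueError):
            wald_intervals(fit1, level=1.2)

    def test_width_shrinks_with_n(self):
        truth = ELGParams(2.0, 1.0, 0.5)
        widths = []
        for n in (400, 1600):
            fit = fit_mle(elg_rvs(n, truth, seed=99), init=truth)
            ci = wald_intervals(fit)
            widths.append(ci["theta"][1] - ci["theta"][0])
        # O(n^{-1/2}): quadrupling n should roughly halve the width
        assert widths[1] < 0.75 * widths[0]


class TestLrTest:
    def test_published_lg_vs_elg(self, data1):
        res = lr_test(data1, "lg")
        assert res.omega == pytest.approx(0.5645, abs=0.02)
        assert res.p_value == pytest.approx(0.4525, abs=0.005)
        assert res.df == 1

    def test_null_equals_full(self, data1, fit1):
        a, t, p = fit1.params_hat.as_tuple()
        res = lr_test(data1, {"alpha": a, "theta": t, "p": p})
        assert res.omega == pytest.approx(0.0, abs=1e-5)
        assert res.p_value == pytest.approx(1.0, abs=1e-5)

    def test_lindley_shortcut(self, data2):
        res = lr_test(data2, "lindley")
        assert res.df == 2
        assert res.omega >= 0.0

    def test_unknown_spec(self, data2):
        with pytest.raises(ValueError):
            lr_test(data2, "weibull")

    def test_type_one_error_rate(self):
        # data simulated under LG (alpha = 1): H0 alpha=1 rejected ~5%
        truth = ELGParams(1.0, 1.0, 0.4)
        master = np.random.default_rng(123)
        rejections = 0
        reps = 300
        for _ in range(reps):
            x = elg_rvs(150, truth, rng=master)
            full = fit_mle(x, init=truth, compute_vcov=False)
            restricted = fit_mle(x, init=truth, fixed={"alpha": 1.0}, compute_vcov=False)
            omega = max(2.0 * (full.loglik - restricted.loglik), 0.0)
            rejections += stats.chi2.sf(omega, 1) < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 0.04


class TestCensored:
    def test_reduction_to_uncensored(self, data2, fit2):
        cs = CensoredSample(exact=data2.times)
        assert censored_loglik(cs, fit2.params_hat) == pytest.approx(
            elg_loglik(data2, fit2.params_hat), abs=1e-12
        )

    def test_interval_mass_two_ways(self):
        params = ELGParams(2.0, 1.0, 0.5)
        s0, s1 = 0.7, 1.9
        mass_cdf = elg_cdf(s1, params) - elg_cdf(s0, params)
        mass_quad = integrate.quad(lambda x: elg_pdf(x, params), s0, s1, limit=200)[0]
        assert mass_cdf == pytest.approx(mass_quad, abs=1e-8)
        cs = CensoredSample(intervals=[(s0, s1)])
        assert censored_loglik(cs, params) == pytest.approx(np.log(mass_cdf), abs=1e-10)

    def test_right_censored_terms(self):
        params = ELGParams(2.0, 1.0, 0.5)
        cs = CensoredSample(right_censored=[1.0, 3.0])
        expect = float(np.sum(np.log([1 - elg_cdf(1.0, params), 1 - elg_cdf(3.0, params)])))
        assert censored_loglik(cs, params) == pytest.approx(expect, abs=1e-10)

    def test_validation(self):
        with pytest.raises(ValueError):
            CensoredSample(intervals=[(2.0, 1.0)])
        with pytest.raises(ValueError):
            CensoredSample(exact=[-1.0])
        with pytest.raises(ValueError):
            CensoredSample()

    def test_recovery_under_right_censoring(self):
        truth = ELGParams(2.0, 1.0, 0.5)
        full = elg_rvs(2000, truth, seed=31).times
        c = np.quantile(full, 0.7)
        cs = CensoredSample(exact=full[full <= c], right_censored=np.full((full > c).sum(), c))
        fit = fit_mle_censored(cs, init=truth)
        # 3 SE yardstick from a finite-difference Hessian of the censored
        # log-likelihood (the package itself does not provide censored SEs)
        v0 = np.array(fit.params_hat.as_tuple())
        h = np.maximum(np.abs(v0), 1e-2) * 1e-4
        hess = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                acc = 0.0
                for si, sj, sgn in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
                    v = v0.copy()
                    v[i] += si * h[i]
                    v[j] += sj * h[j]
                    acc += sgn * censored_loglik(cs, ELGParams(*v))
                hess[i, j] = acc / (4.0 * h[i] * h[j])
        se = np.sqrt(np.diag(np.linalg.inv(-hess)))
        assert np.all(np.abs(v0 - np.array(truth.as_tuple())) < 3.0 * se)

    def test_em_direct_agreement_on_simulations(self):
        # interior-p design: the latent-geometric EM cannot reach p <= 0, so
        # agreement with the unconstrained MLE is only meaningful when the
        # optimum is interior
        truth = ELGParams(2.0, 1.0, 0.7)
        master = np.random.default_rng(303)
        for _ in range(5):
            x = elg_rvs(300, truth, rng=master)
            em = fit_em(x, init=truth, compute_vcov=False)
            direct = fit_mle(x, init=truth, compute_vcov=False)
            diff = np.abs(
                np.array(em.params_hat.as_tuple()) - np.array(direct.params_hat.as_tuple())
            )
            assert np.all(diff < 1e-3)
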