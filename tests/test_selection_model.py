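import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from sportsel.copulas import FrankDependence
from sportsel.margins import DesignError, DurationMargin, ParticipationMargin
from sportsel.selection_model import (
    ConvergenceError,
    FitResult,
    LikelihoodError,
    ModelParams,
    SelectionDataset,
    _central_hessian,
    fit,
    likelihood_ratio,
    log_likelihood,
    lr_test,
    standard_errors,
)
from sportsel.synthetic_data import generate_dataset

from conftest import DUR_NAMES, PART_NAMES, small_spec, small_truth


def tiny_dataset(n=5, seed=0, theta=4.0):
    data, _ = generate_dataset(small_spec(200, seed=seed, theta=theta))
    # carve out the first n rows keeping at least one of each status
    idx = np.concatenate(
        [np.flatnonzero(data.s == 1)[: max(1, n - 2)], np.flatnonzero(data.s == 0)[:2]]
    )[:n]
    return SelectionDataset(
        s=data.s[idx],
        t=data.t[idx],
        q=data.q[idx],
        X_part=data.X_part[idx],
        X_dur=data.X_dur[idx],
        part_names=data.part_names,
        dur_names=data.dur_names,
    )


def naive_likelihood(params, data):
    """Literal product-form implementation with scalar math (oracle)."""
    L = 1.0
    th = params.dependence.theta
    for i in range(data.n):
        xb = float(data.X_part[i] @ params.participation.beta)
        F0 = stats.norm.cdf(-xb)
        if data.s[i] == 0:
            L *= F0
        else:
            shape = params.duration.alpha * data.q[i]
            lam = math.exp(float(data.X_dur[i] @ params.duration.gamma))
            G = stats.gamma.cdf(data.t[i], a=shape, scale=lam)
            g = stats.gamma.pdf(data.t[i], a=shape, scale=lam)
            C = -math.log(
                1.0
                + (math.exp(-th * F0) - 1.0)
                * (math.exp(-th * G) - 1.0)
                / (math.exp(-th) - 1.0)
            ) / th
            phi_G = th / (1.0 - math.exp(th * G))
            phi_C = th / (1.0 - math.exp(th * C))
            L *= (1.0 - phi_G / phi_C) * g
    return L


class TestLogLikelihood:
    def test_exp_equals_naive_product_on_five_rows(self):
        data = tiny_dataset(5)
        params = small_truth(theta=4.0)
        got = math.exp(log_likelihood(params, data))
        assert got == pytest.approx(naive_likelihood(params, data), rel=1e-9)

    def test_nonparticipant_contribution_is_log_complement(self):
        # single s = 0 respondent with Phi(x'beta) = 0.7 contributes log 0.3
        xb = stats.norm.ppf(0.7)
        data = SelectionDataset(
            s=np.array([0]),
            t=np.array([np.nan]),
            q=np.array([np.nan]),
            X_part=np.array([[1.0]]),
            X_dur=np.array([[1.0]]),
            part_names=["constant"],
            dur_names=["constant"],
        )
        params = ModelParams(
            participation=ParticipationMargin(np.array([xb]), ["constant"]),
            duration=DurationMargin(np.array([0.0]), 1.0, ["constant"]),
            dependence=FrankDependence(2.0),
            family="frank",
        )
        assert log_likelihood(params, data) == pytest.approx(math.log(0.3), rel=1e-10)

    def test_theta_to_zero_matches_independence(self):
        data, _ = generate_dataset(small_spec(200, seed=1))
        frank = small_truth(theta=1e-9, family="frank")
        indep = small_truth(theta=0.0, family="independence")
        assert log_likelihood(frank, data) == pytest.approx(
            log_likelihood(indep, data), abs=1e-4
        )

    @pytest.mark.parametrize("theta", [0.0, 2.0, 5.597, -3.0])
    def test_participant_term_integrates_to_participation_prob(self, theta):
        # total probability: integrating the participant integrand over all
        # durations recovers Phi(x'beta)
        params = small_truth(theta=theta if theta else 1e-12)
        xb, q = 0.4, 3.0
        shape = params.duration.alpha * q
        lam = 1.8
        dep = FrankDependence(theta)
        F0 = stats.norm.cdf(-xb)

        def integrand(t):
            G = stats.gamma.cdf(t, a=shape, scale=lam)
            g = stats.gamma.pdf(t, a=shape, scale=lam)
            if dep.is_independent:
                return (1.0 - F0) * g
            from sportsel.copulas import frank_cdf, generator_derivative

            C = frank_cdf(F0, min(G, 1.0 - 1e-15), dep)
            ratio = generator_derivative(max(G, 1e-300), dep) / generator_derivative(
                max(C, 1e-300), dep
            )
            return (1.0 - ratio) * g

        total, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
        assert total == pytest.approx(stats.norm.cdf(xb), abs=1e-6)

    def test_nonfinite_contribution_flags_respondent(self):
        data = tiny_dataset(5)
        params = ModelParams(
            participation=small_truth().participation,
            duration=DurationMargin(
                np.array([800.0, 0.0, 0.0, 0.0, 0.0]), 0.25, DUR_NAMES
            ),  # scale overflows to inf -> nan logpdf
            dependence=FrankDependence(5.0),
            family="frank",
        )
        with pytest.raises(LikelihoodError, match="respondent"):
            log_likelihood(params, data)


class TestFit:
    def test_independence_fit_matches_single_equation_fits(self, sim5000):
        # oracle route: statsmodels probit + a separate Gamma-margin MLE
        import statsmodels.api as sm
        from scipy.optimize import minimize

        data, _ = sim5000
        res = fit(data, family="independence", compute_se=False)

        probit = sm.Probit(data.s, data.X_part).fit(disp=0)
        np.testing.assert_allclose(
            res.params.participation.beta, probit.params, atol=1e-5
        )

        part = data.s == 1
        t, q, X = data.t[part], data.q[part], data.X_dur[part]

        def neg_gamma_ll(vec):
            gamma, log_alpha = vec[:-1], vec[-1]
            shape = np.exp(log_alpha) * q
            lam = np.exp(X @ gamma)
            return -stats.gamma.logpdf(t, a=shape, scale=lam).sum()

        x0 = np.append(res.params.duration.gamma, np.log(res.params.duration.alpha))
        ref = minimize(neg_gamma_ll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
        np.testing.assert_allclose(res.params.duration.gamma, ref.x[:-1], atol=1e-4)
        assert res.params.duration.alpha == pytest.approx(np.exp(ref.x[-1]), abs=1e-4)

    def test_frank_recovers_truth_within_three_se(self, fit5000):
        _, res = fit5000
        truth = small_truth(theta=5.0)
        est = np.concatenate(
            [
                res.params.participation.beta,
                res.params.duration.gamma,
                [res.params.duration.alpha, res.params.dependence.theta],
            ]
        )
        true = np.concatenate(
            [
                truth.participation.beta,
                truth.duration.gamma,
                [truth.duration.alpha, truth.dependence.theta],
            ]
        )
        ses = np.array(
            [res.se[("participation", n)] for n in PART_NAMES]
            + [res.se[("duration", n)] for n in DUR_NAMES]
            + [res.se[("duration", "alpha")], res.se[("copula", "theta")]]
        )
        assert np.all(np.abs(est - true) <= 3.0 * ses)

    def test_frank_loglik_at_least_independence(self, fit5000):
        res_i, res_f = fit5000
        assert res_f.loglik >= res_i.loglik - 1e-6

    def test_optimum_beats_truth(self, fit5000, sim5000):
        data, _ = sim5000
        _, res_f = fit5000
        assert res_f.loglik >= log_likelihood(small_truth(theta=5.0), data)

    def test_loglik_trace_monotone(self, fit5000):
        _, res_f = fit5000
        trace = np.array(res_f.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_null_data_gives_small_theta_and_lr(self):
        data, _ = generate_dataset(small_spec(2000, seed=9, theta=0.0))
        res_i = fit(data, family="independence", compute_se=False)
        res_f = fit(data, family="frank", start=res_i.params, compute_se=False)
        stat, df, p = lr_test(res_i, res_f)
        assert df == 1
        assert stat < 8.0  # chi2(1) upper tail under the null
        assert abs(res_f.params.dependence.theta) < 1.5

    def test_scale_consistency(self):
        # multiplying durations by c shifts only the duration intercept by log c
        c = 3.0
        data, table = generate_dataset(small_spec(1200, seed=5))
        res = fit(data, family="frank", compute_se=False)
        scaled = SelectionDataset(
            s=data.s, t=data.t * c, q=data.q,
            X_part=data.X_part, X_dur=data.X_dur,
            part_names=data.part_names, dur_names=data.dur_names,
        )
        res_c = fit(scaled, family="frank", compute_se=False)
        np.testing.assert_allclose(
            res_c.params.participation.beta, res.params.participation.beta, atol=1e-4
        )
        assert res_c.params.duration.alpha == pytest.approx(
            res.params.duration.alpha, abs=1e-4
        )
        assert res_c.params.dependence.theta == pytest.approx(
            res.params.dependence.theta, abs=5e-3
        )
        shift = res_c.params.duration.gamma - res.params.duration.gamma
        assert shift[0] == pytest.approx(np.log(c), abs=1e-4)
        np.testing.assert_allclose(shift[1:], 0.0, atol=1e-4)

    def test_rank_deficient_design_rejected(self):
        data, _ = generate_dataset(small_spec(200, seed=2))
        X = np.column_stack([data.X_part, data.X_part[:, -1]])
        bad = SelectionDataset(
            s=data.s, t=data.t, q=data.q, X_part=X, X_dur=data.X_dur,
            part_names=list(data.part_names) + ["dup"], dur_names=data.dur_names,
        )
        with pytest.raises(DesignError, match="rank"):
            fit(bad, family="frank")

    def test_minimum_sample_size(self):
        data = tiny_dataset(5)
        with pytest.raises(ValueError, match="20"):
            fit(data)


class TestStandardErrors:
    def test_quadratic_toy_closed_form(self):
        # Hessian helper on a known quadratic: f(x) = -0.5 x'Ax has
        # curvature -A, so the implied covariance is A^{-1}
        A = np.array([[2.0, 0.3], [0.3, 1.0]])
        H = _central_hessian(lambda x: -0.5 * x @ A @ x, np.array([0.2, -0.1]))
        np.testing.assert_allclose(-H, A, atol=1e-6)
        np.testing.assert_allclose(np.linalg.inv(-H), np.linalg.inv(A), atol=1e-5)

    def test_permutation_invariance(self):
        data, _ = generate_dataset(small_spec(400, seed=3))
        params = small_truth(theta=5.0)
        se1 = standard_errors(params, data)
        perm = np.random.default_rng(0).permutation(data.n)
        shuffled = SelectionDataset(
            s=data.s[perm], t=data.t[perm], q=data.q[perm],
            X_part=data.X_part[perm], X_dur=data.X_dur[perm],
            part_names=data.part_names, dur_names=data.dur_names,
        )
        se2 = standard_errors(params, shuffled)
        # summation order perturbs the finite-difference Hessian at the
        # level of accumulated roundoff; 1e-4 relative is the honest bound
        for key in se1:
            assert se1[key] == pytest.approx(se2[key], rel=1e-4)

    def test_all_positive_at_optimum(self, fit5000):
        _, res_f = fit5000
        assert res_f.hessian_pd
        assert all(v > 0 for v in res_f.se.values())
        assert res_f.tau_se is not None and res_f.tau_se > 0


class TestLrTest:
    def test_published_logliks_give_286(self, fixtures):
        stat, df, p = likelihood_ratio(
            fixtures.loglik["independence"], fixtures.loglik["frank"]
        )
        assert round(stat) == 286 and df == 1 and p < 1e-10

    def test_identical_fits_give_zero(self, fit5000):
        res_i, _ = fit5000
        r = FitResult(**{**res_i.__dict__})
        f = FitResult(**{**res_i.__dict__})
        f.params = ModelParams(
            participation=res_i.params.participation,
            duration=res_i.params.duration,
            dependence=FrankDependence(0.0),
            family="frank",
        )
        stat, df, _ = lr_test(r, f)
        assert stat == pytest.approx(0.0, abs=1e-9)

    def test_non_nested_usage_error(self, fit5000):
        res_i, res_f = fit5000
        with pytest.raises(ValueError, match="nested"):
            lr_test(res_f, res_i)


class TestDatasetValidation:
    def test_participant_invariants(self):
        with pytest.raises(ValueError):
            SelectionDataset(
                s=np.array([1]), t=np.array([0.0]), q=np.array([1.0]),
                X_part=np.ones((1, 1)), X_dur=np.ones((1, 1)),
                part_names=["constant"], dur_names=["constant"],
            )

    def test_from_table_drops_zero_durations(self, caplog):
        table = pd.DataFrame(
            {
                "s": [1, 1, 0], "t": [0.0, 2.0, np.nan], "q": [1.0, 2.0, np.nan],
                "x1": [0.0, 1.0, 0.5], "x2": [1.0, 0.0, 0.5], "x3": [0.0, 0.0, 1.0],
                "vigour_moderate": [0.0, 1.0, 0.0], "vigour_high": [0.0, 0.0, 0.0],
            }
        )
        data = SelectionDataset.from_table(table, PART_NAMES, DUR_NAMES)
        assert data.n == 2 and data.n_dropped_zero_duration == 1
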