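"""Newton fitting, score/information oracles, sandwich covariance, df."""

import numpy as np
import pytest

from penmpr import (
    MprParameters,
    PenaltyConfig,
    SurvivalDataset,
    fit_penalized,
    fit_unpenalized,
    log_likelihood,
    score_and_information,
)
from penmpr.penalties import effective_lambda, penalty_value
from penmpr.simulation import SimulationScenario, generate_dataset

from conftest import make_weibull_dataset


def _pen_objective(theta, data, lam, config):
    params = MprParameters.from_theta(theta, data.p + 1)
    pen = penalty_value(params.theta, lam, config)
    return log_likelihood(params, data) - data.n * float(np.sum(pen))


def _fd_gradient(theta, data, lam, config, h=1e-6):
    g = np.empty_like(theta)
    for j in range(theta.size):
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        g[j] = (
            _pen_objective(up, data, lam, config)
            - _pen_objective(dn, data, lam, config)
        ) / (2 * h)
    return g


def _fd_hessian(theta, data, lam, config, h=1e-5):
    k = theta.size
    hess = np.empty((k, k))
    for j in range(k):
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        gu = _fd_gradient(up, data, lam, config, h=1e-6)
        gd = _fd_gradient(dn, data, lam, config, h=1e-6)
        hess[:, j] = (gu - gd) / (2 * h)
    return (hess + hess.T) / 2.0


NO_PEN = PenaltyConfig(family="lasso", structure="single")


class TestScoreInformationOracles:
    """The central correctness check: analytic score/curvature vs FD."""

    def test_unpenalized_score_and_information_match_fd(self, small_dataset):
        rng = np.random.default_rng(8)
        theta = rng.normal(0, 0.3, small_dataset.p + small_dataset.q + 2)
        params = MprParameters.from_theta(theta, small_dataset.p + 1)
        lam = np.zeros(theta.size)
        grad, info, i0 = score_and_information(params, small_dataset, lam)
        fd_g = _fd_gradient(theta, small_dataset, lam, NO_PEN)
        fd_h = -_fd_hessian(theta, small_dataset, lam, NO_PEN)
        assert np.allclose(grad, fd_g, rtol=1e-5, atol=1e-5)
        assert np.allclose(info, fd_h, rtol=1e-4, atol=5e-3)
        assert np.allclose(info, i0)

    @pytest.mark.parametrize(
        "family,lam_raw",
        [("lasso", 0.05), ("alasso", 0.05), ("scad", 0.01)],
        # scad evaluated with all coefficients outside its concave region,
        # where the reported (floored) curvature equals the literal one
    )
    def test_penalized_gradient_and_hessian_match_fd(self, family, lam_raw):
        data = make_weibull_dataset(n=30, seed=21)
        kw = {"adaptive_weights": (np.array([0.7, 1.4]), np.array([2.0, 0.4]))} \
            if family == "alasso" else {}
        config = PenaltyConfig(family=family, structure="single", **kw)
        rng = np.random.default_rng(4)
        theta = rng.normal(0, 0.5, data.p + data.q + 2)
        if family == "scad":
            theta[np.abs(theta) < 0.2] = 0.3  # clear of (lam, a*lam)
        lam = effective_lambda(config, [lam_raw], data.p, data.q)
        params = MprParameters.from_theta(theta, data.p + 1)
        grad, info, _ = score_and_information(params, data, lam, config)
        fd_g = _fd_gradient(theta, data, lam, config)
        fd_h = -_fd_hessian(theta, data, lam, config)
        assert np.allclose(grad, fd_g, rtol=1e-5, atol=1e-5)
        assert np.allclose(info, fd_h, rtol=1e-4, atol=5e-3)

    def test_exponential_submodel_score_reduces_to_glm_form(self):
        """With gamma = 1 the scale score is X'(delta - tau*t)."""
        data = make_weibull_dataset(n=40, seed=3, q=1)
        params = MprParameters(
            beta=np.array([-0.4, 0.2, -0.1]), alpha=np.zeros(2)
        )
        lam = np.zeros(5)
        grad, _, _ = score_and_information(params, data, lam)
        tau = np.exp(data.scale_design @ params.beta)
        expected = data.scale_design.T @ (data.events - tau * data.times)
        assert np.allclose(grad[:3], expected, rtol=1e-12)

    def test_gradient_vanishes_at_unpenalized_mle(self, medium_dataset):
        fit = fit_unpenalized(medium_dataset)
        grad, _, _ = score_and_information(
            fit.params_std, medium_dataset, np.zeros(fit.n_params)
        )
        assert np.max(np.abs(grad)) < 1e-5


class TestUnpenalizedFit:
    def test_intercept_only_exponential_closed_form(self):
        """gamma=1 truth, no covariates: tau_hat = sum(delta)/sum(t)."""
        rng = np.random.default_rng(11)
        t = rng.exponential(2.0, size=200)
        data = SurvivalDataset(
            times=t,
            events=np.ones(200),
            scale_design=np.ones((200, 1)),
            shape_design=np.ones((200, 1)),
        )
        # freeze the shape at gamma=1 by fitting the scale-only submodel
        fit = fit_unpenalized(data)
        # full model: still check the implied closed form when gamma_hat ~ 1
        tau_closed = np.sum(data.events) / np.sum(data.times)
        gam_hat = float(np.exp(fit.params_std.alpha[0]))
        if abs(gam_hat - 1.0) < 0.05:
            t_pow = data.times ** gam_hat
            tau_stat = np.sum(data.events) / np.sum(t_pow)
            assert np.exp(fit.params_std.beta[0]) == pytest.approx(
                tau_stat, abs=1e-6
            )
        assert np.exp(fit.params_std.beta[0]) == pytest.approx(
            tau_closed, rel=0.1
        )

    def test_parameter_recovery_large_sample(self):
        scenario = SimulationScenario(n=5000, n_replicates=1, seed=77)
        data = generate_dataset(scenario, 123456)
        fit = fit_unpenalized(data)
        truth = np.concatenate([scenario.beta_true, scenario.alpha_true])
        z = (fit.coefficients() - truth) / fit.standard_errors
        assert np.all(np.abs(z) < 4.0)

    def test_refit_from_solution_is_idempotent(self, medium_dataset):
        fit = fit_unpenalized(medium_dataset)
        refit = fit_unpenalized(medium_dataset, init=fit.params_std)
        assert refit.n_iter == 1
        assert np.allclose(
            refit.params_std.theta, fit.params_std.theta, atol=1e-8
        )

    def test_warns_when_underdetermined(self):
        data = make_weibull_dataset(n=8, p=3, q=3, seed=2)
        with pytest.warns(UserWarning, match="unstable"):
            fit_unpenalized(data, max_iter=2)


class TestPenalizedFit:
    def test_zero_lambda_equals_unpenalized(self, medium_dataset):
        unpen = fit_unpenalized(medium_dataset)
        pen = fit_penalized(medium_dataset, [0.0], NO_PEN, init=unpen.params_std)
        assert np.allclose(
            pen.params_std.theta, unpen.params_std.theta, atol=1e-8
        )
        assert pen.effective_df == pytest.approx(unpen.effective_df, abs=1e-9)

    def test_huge_lambda_kills_all_slopes(self, medium_dataset):
        unpen = fit_unpenalized(medium_dataset)
        fit = fit_penalized(medium_dataset, [1e3], NO_PEN, init=unpen.params_std)
        assert not fit.active_scale[1:].any()
        assert not fit.active_shape[1:].any()
        assert fit.active_scale[0] and fit.active_shape[0]

    @pytest.mark.parametrize("family", ["lasso", "scad"])
    def test_stationarity_of_returned_solution(self, family):
        data = make_weibull_dataset(n=120, seed=31)
        config = PenaltyConfig(family=family, structure="single")
        unpen = fit_unpenalized(data)
        fit = fit_penalized(data, [0.05], config, init=unpen.params_std)
        assert fit.converged
        grad, _, _ = score_and_information(
            fit.params_std, data, fit.lambda_used, config
        )
        assert np.max(np.abs(grad)) < 1e-5

    def test_ascent_from_initial_value(self, medium_dataset):
        unpen = fit_unpenalized(medium_dataset)
        config = PenaltyConfig(family="lasso", structure="single")
        fit = fit_penalized(medium_dataset, [0.08], config,
                            init=unpen.params_std)
        lam = fit.lambda_used
        init_obj = _pen_objective(unpen.params_std.theta, medium_dataset,
                                  lam, config)
        assert fit.penalized_objective >= init_obj - 1e-9

    def test_equivariance_standardized_vs_raw(self):
        raw = make_weibull_dataset(n=250, seed=17, standardize=False)
        std = SurvivalDataset.from_covariates(
            raw.times, raw.events, raw.scale_design[:, 1:],
            raw.shape_design[:, 1:], standardize=True,
        )
        fit_raw = fit_unpenalized(raw)
        fit_std = fit_unpenalized(std)
        assert np.allclose(
            fit_std.coefficients(), fit_raw.coefficients(), atol=1e-6
        )
        assert np.allclose(
            fit_std.standard_errors, fit_raw.standard_errors, atol=1e-6
        )


class TestCovarianceAndDf:
    def test_sandwich_reduces_to_inverse_information_at_zero_lambda(
        self, medium_dataset
    ):
        fit = fit_unpenalized(medium_dataset)
        expected = np.linalg.inv(fit.info_unpenalized)
        assert np.allclose(fit.covariance_std, expected, rtol=1e-10)

    def test_covariance_symmetric_psd(self, medium_dataset):
        unpen = fit_unpenalized(medium_dataset)
        fit = fit_penalized(
            medium_dataset, [0.05], NO_PEN, init=unpen.params_std
        )
        cov = fit.covariance
        assert np.allclose(cov, cov.T)
        assert np.min(np.linalg.eigvalsh(cov)) > -1e-10

    def test_shrinkage_reduces_reported_variance(self, medium_dataset):
        """Typical (not universal) behaviour: the penalized coefficients'
        reported variances shrink; intercepts are unpenalized and exempt."""
        unpen = fit_unpenalized(medium_dataset)
        fit = fit_penalized(
            medium_dataset, [0.3], NO_PEN, init=unpen.params_std
        )
        slopes = np.r_[1 : medium_dataset.p + 1,
                       medium_dataset.p + 2 : fit.n_params]
        assert np.all(
            np.diag(fit.covariance_std)[slopes]
            <= np.diag(unpen.covariance_std)[slopes] + 1e-9
        )

    def test_df_equals_parameter_count_at_zero_lambda(self, medium_dataset):
        fit = fit_unpenalized(medium_dataset)
        assert fit.effective_df == pytest.approx(
            medium_dataset.p + medium_dataset.q + 2, abs=1e-9
        )

    def test_df_approaches_intercept_count_at_large_lambda(self, medium_dataset):
        unpen = fit_unpenalized(medium_dataset)
        fit = fit_penalized(
            medium_dataset, [1e3], NO_PEN, init=unpen.params_std
        )
        assert fit.effective_df == pytest.approx(2.0, abs=0.1)

    def test_df_monotone_along_lambda_path(self, medium_dataset):
        unpen = fit_unpenalized(medium_dataset)
        dfs = []
        for lam in [0.0, 0.01, 0.05, 0.1, 0.5, 2.0, 20.0]:
            fit = fit_penalized(
                medium_dataset, [lam], NO_PEN, init=unpen.params_std
            )
            dfs.append(fit.effective_df)
        assert all(b <= a + 1e-6 for a, b in zip(dfs, dfs[1:]))
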