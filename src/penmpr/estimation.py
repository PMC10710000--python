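"""Penalized and unpenalized fitting of the Weibull MPR model.

The penalized log-likelihood is

    l(theta) = l0(theta) - n * sum_j J_{lam_bj}(|beta_j|)
                         - n * sum_j J_{lam_aj}(|alpha_j|)

with intercepts unpenalized.  Maximization solves the Newton-Raphson block
system

    [X'WbX + n*Sb   X'Wab Z ] [d_beta ]   [X'Ub - n*Vb]
    [Z'Wab X   Z'WaZ + n*Sa ] [d_alpha] = [Z'Ua - n*Va]

iteratively, where Ub_i = delta_i - tau_i t_i^gamma_i,
Ua_i = delta_i(1 + gamma_i log t_i) - tau_i gamma_i t_i^gamma_i log t_i, the
W diagonals are tau t^gamma, {tau t^gamma (gamma log t + 1) - delta} gamma
log t and tau gamma t^gamma log t, and V / Sigma hold the penalty's first and
second derivatives.  A step-halving line search guarantees ascent of the
penalized objective, and indefinite systems are handled by Levenberg-style
diagonal inflation.  Inference uses the sandwich covariance
I(theta)^-1 I0(theta) I(theta)^-1 and the effective degrees of freedom
tr[I(theta)^-1 I0(theta)].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg

from .model import (
    PREDICTOR_CLIP as CLIP,
    MprParameters,
    SurvivalDataset,
    _clip_predictor,
    log_likelihood,
)
from . import _kernels
from .penalties import (
    PenaltyConfig,
    effective_lambda,
    penalty_iteration_curvature,
    penalty_terms,
)

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100
MAX_HALVINGS = 20

_NO_PENALTY = PenaltyConfig(family="lasso", structure="single")


@dataclass
class FittedModel:
    """A fitted (possibly penalized) Weibull MPR model.

    Coefficients are kept on the standardized scale used during optimization
    (``params_std``) and back-transformed to the original covariate units
    (``params_orig``); the sandwich covariance and standard errors are
    reported on the original scale, ``covariance_std`` on the standardized
    one.  ``active_scale`` / ``active_shape`` flag coefficients whose
    standardized magnitude exceeds the zero threshold (intercepts always
    active).
    """

    params_std: MprParameters
    params_orig: MprParameters
    covariance: np.ndarray
    covariance_std: np.ndarray
    loglik_unpenalized: float
    penalized_objective: float
    effective_df: float
    lambda_used: np.ndarray
    active_scale: np.ndarray
    active_shape: np.ndarray
    n_iter: int
    converged: bool
    standard_errors: np.ndarray
    n_obs: int
    zero_threshold: float = 1e-3
    info_penalized: np.ndarray = field(default=None, repr=False)
    info_unpenalized: np.ndarray = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return self.params_std.beta.shape[0] + self.params_std.alpha.shape[0]

    def coefficients(self, zero_inactive: bool = False) -> np.ndarray:
        """Original-scale theta; optionally report de-selected slopes as 0."""
        theta = self.params_orig.theta.copy()
        if zero_inactive:
            active = np.concatenate([self.active_scale, self.active_shape])
            theta[~active] = 0.0
        return theta


class _FitWorkspace:
    """Precomputed arrays and fused objective/score/information evaluations.

    The Newton loop evaluates the penalized objective once per line-search
    trial and the score/information once per iteration; sharing the
    per-subject Weibull quantities and the one-pass penalty terms keeps each
    iteration to a handful of length-n vector operations plus three small
    cross-products.
    """

    def __init__(self, data: SurvivalDataset, lam: np.ndarray,
                 config: PenaltyConfig):
        self.X = data.scale_design
        self.Z = data.shape_design
        self.d = data.events
        self.logt = np.log(data.times)
        self.n = data.n
        self.nb = data.p + 1
        self.lam = np.asarray(lam, dtype=float)
        self.config = config
        if self.lam.shape[0] != data.p + data.q + 2:
            raise ValueError(
                f"lambda vector must have length {data.p + data.q + 2}"
            )
        self._memo_theta = None
        self._memo = None

    def _quants(self, theta: np.ndarray):
        # identity-keyed memo: the accepted line-search trial and the next
        # iteration's score evaluate the same theta object
        if self._memo_theta is theta:
            return self._memo
        eta_s = np.clip(self.X @ theta[: self.nb], -CLIP, CLIP)
        eta_a = np.clip(self.Z @ theta[self.nb :], -CLIP, CLIP)
        gam = np.exp(eta_a)
        glt = gam * self.logt
        mu = np.exp(np.minimum(eta_s + glt, CLIP))
        self._memo_theta = theta
        self._memo = (eta_s, eta_a, gam, glt, mu)
        return self._memo

    def loglik(self, theta: np.ndarray) -> float:
        eta_s, eta_a, _, glt, mu = self._quants(theta)
        return float(
            np.sum(self.d * (eta_s + eta_a + glt - self.logt) - mu)
        )

    def objective(self, theta: np.ndarray) -> float:
        val, _, _ = penalty_terms(theta, self.lam, self.config)
        return self.loglik(theta) - self.n * float(np.sum(val))

    def check_clipping(self, theta: np.ndarray) -> None:
        """Log (once per label) if the solution's predictors sit at the guard."""
        _clip_predictor(self.X @ theta[: self.nb], "scale")
        _clip_predictor(self.Z @ theta[self.nb :], "shape")

    def score_info(self, theta: np.ndarray, check: bool = False,
                   iter_matrix: bool = False):
        """(penalized gradient, penalized information, unpenalized information).

        With ``iter_matrix=True`` the penalty curvature diagonal is the
        secant J'(theta)/theta used to drive the Newton iteration; reported
        information (df, sandwich) always uses the literal curvature floored
        at zero.
        """
        _, _, _, glt, mu = self._quants(theta)
        d, n, nb = self.d, self.n, self.nb
        u_beta = d - mu
        u_alpha = d * (1.0 + glt) - mu * glt
        w_beta = mu
        w_alpha = (mu * (glt + 1.0) - d) * glt
        w_ab = mu * glt
        if check:
            for name, w in (("W_beta", w_beta), ("W_alpha", w_alpha),
                            ("W_alphabeta", w_ab)):
                if not np.all(np.isfinite(w)):
                    bad = int(np.nonzero(~np.isfinite(w))[0][0])
                    raise FloatingPointError(
                        f"non-finite {name} entry at subject index {bad}"
                    )
        X, Z = self.X, self.Z
        _, v, sig = penalty_terms(theta, self.lam, self.config)
        if iter_matrix:
            sig = penalty_iteration_curvature(theta, self.lam, self.config)
        else:
            # SCAD's concave region has negative literal curvature, which
            # can make the penalized information indefinite and destabilize
            # the df/sandwich traces; the reported curvature diagonal is
            # floored at zero (the score, hence the fitted point, is exact)
            sig = np.maximum(sig, 0.0)
        k = theta.shape[0]
        grad = np.empty(k)
        grad[:nb] = X.T @ u_beta - n * v[:nb]
        grad[nb:] = Z.T @ u_alpha - n * v[nb:]
        i0 = np.empty((k, k))
        i0[:nb, :nb] = X.T @ (w_beta[:, None] * X)
        i0[:nb, nb:] = X.T @ (w_ab[:, None] * Z)
        i0[nb:, :nb] = i0[:nb, nb:].T
        i0[nb:, nb:] = Z.T @ (w_alpha[:, None] * Z)
        info = i0 + np.diag(n * sig)
        return grad, info, i0


def score_and_information(
    params: MprParameters,
    data: SurvivalDataset,
    lambda_vector: np.ndarray,
    config: PenaltyConfig = _NO_PENALTY,
):
    """Penalized score, penalized information I, unpenalized information I0.

    ``lambda_vector`` is the per-coefficient effective tuning vector of
    length p+q+2 (intercept slots zero, ALASSO weights already folded in).
    """
    ws = _FitWorkspace(data, lambda_vector, config)
    return ws.score_info(params.theta, check=True)


def _solve_ascent(info, grad):
    """Newton direction with Levenberg-style inflation until it is an ascent."""
    ridge = 0.0
    scale = max(float(np.mean(np.abs(np.diag(info)))), 1e-8)
    for _ in range(30):
        try:
            step = linalg.solve(info + ridge * scale * np.eye(info.shape[0]),
                                grad, assume_a="sym")
        except linalg.LinAlgError:
            step = None
        if step is not None and np.all(np.isfinite(step)) and grad @ step > 0:
            return step
        ridge = 1e-8 if ridge == 0.0 else ridge * 10.0
    # fall back to (damped) gradient ascent
    logger.warning("information matrix irreparably indefinite; gradient step used")
    return grad / (scale + 1.0)


def _newton(data, lam, config, init_theta, max_iter, tol):
    """Core ascent loop shared by unpenalized and penalized fits.

    Dispatches to the compiled kernel when numba is importable; the pure
    NumPy loop below is the reference implementation and fallback.
    """
    if _kernels.NUMBA_AVAILABLE:
        family = (_kernels.FAMILY_SCAD if config.family == "scad"
                  else _kernels.FAMILY_L1)
        theta, obj, it, conv = _kernels.newton_core(
            data.scale_design, data.shape_design, data.events,
            np.log(data.times), np.asarray(lam, dtype=float), family,
            config.scad_a, config.epsilon,
            np.asarray(init_theta, dtype=float), max_iter, tol, MAX_HALVINGS,
        )
        _FitWorkspace(data, lam, config).check_clipping(theta)
        return MprParameters.from_theta(theta, data.p + 1), obj, it, conv
    ws = _FitWorkspace(data, lam, config)
    theta = np.asarray(init_theta, dtype=float).copy()
    obj = ws.objective(theta)
    converged = False
    secant = bool(np.any(np.asarray(lam) > 0))
    it = 0
    for it in range(1, max_iter + 1):
        grad, info, _ = ws.score_info(theta, iter_matrix=secant)
        step = _solve_ascent(info, grad)
        factor = 1.0
        accepted = False
        for _ in range(MAX_HALVINGS):
            cand = theta + factor * step
            cand_obj = ws.objective(cand)
            if np.isfinite(cand_obj) and cand_obj >= obj - 1e-12:
                accepted = True
                break
            factor *= 0.5
        if not accepted:
            break
        delta = float(np.max(np.abs(factor * step)))
        theta, obj = cand, cand_obj
        if delta < tol and not secant:
            converged = True
            break
        if delta < 1e-3 and secant:
            secant = False
    ws.check_clipping(theta)
    return MprParameters.from_theta(theta, data.p + 1), obj, it, converged


def _default_init(data: SurvivalDataset) -> np.ndarray:
    """Exponential-rate start: beta0 = log(sum delta / sum t), slopes 0."""
    theta = np.zeros(data.p + data.q + 2)
    rate = max(float(np.sum(data.events)) / float(np.sum(data.times)), 1e-10)
    theta[0] = np.log(rate)
    return theta


def _standardization_jacobian(data: SurvivalDataset) -> np.ndarray:
    """Linear map A with theta_orig = A theta_std (block per component)."""

    def _block(std, k):
        A = np.eye(k + 1)
        if k:
            A[0, 1:] = -std.mean / std.sd
            A[1:, 1:] = np.diag(1.0 / std.sd)
        return A

    return linalg.block_diag(
        _block(data.scale_std, data.p), _block(data.shape_std, data.q)
    )


def _finalize(data, config, lam, params, obj, n_iter, converged) -> FittedModel:
    n_beta = data.p + 1
    _, info, i0 = score_and_information(params, data, lam, config)
    cov_std = sandwich_covariance_matrices(info, i0)
    df = effective_df_matrices(info, i0)
    A = _standardization_jacobian(data)
    cov_orig = A @ cov_std @ A.T
    theta_orig = A @ params.theta
    se = np.sqrt(np.clip(np.diag(cov_orig), 0.0, np.inf))
    zt = config.zero_threshold
    active = np.abs(params.theta) > zt
    active[0] = True
    active[n_beta] = True
    return FittedModel(
        params_std=params,
        params_orig=MprParameters.from_theta(theta_orig, n_beta),
        covariance=cov_orig,
        covariance_std=cov_std,
        loglik_unpenalized=log_likelihood(params, data),
        penalized_objective=obj,
        effective_df=df,
        lambda_used=lam,
        active_scale=active[:n_beta],
        active_shape=active[n_beta:],
        n_iter=n_iter,
        converged=converged,
        standard_errors=se,
        n_obs=data.n,
        zero_threshold=zt,
        info_penalized=info,
        info_unpenalized=i0,
    )


def fit_unpenalized(
    data: SurvivalDataset,
    init: Optional[MprParameters] = None,
    *,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> FittedModel:
    """Maximum-likelihood fit (all tuning parameters zero).

    The covariance reduces to the inverse observed information and the
    effective degrees of freedom to p+q+2 exactly.
    """
    n_par = data.p + data.q + 2
    if data.n <= n_par:
        warnings.warn(
            f"n={data.n} does not exceed the parameter count {n_par}; "
            "the unpenalized fit may be unstable"
        )
    lam = np.zeros(n_par)
    theta0 = init.theta if init is not None else _default_init(data)
    params, obj, it, conv = _newton(data, lam, _NO_PENALTY, theta0, max_iter, tol)
    if not conv:
        logger.warning("unpenalized fit did not converge in %d iterations", it)
    return _finalize(data, _NO_PENALTY, lam, params, obj, it, conv)


def fit_penalized(
    data: SurvivalDataset,
    lambda_raw,
    config: PenaltyConfig,
    init: Optional[MprParameters] = None,
    *,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> FittedModel:
    """Penalized fit at a given raw tuning parameter (1- or 2-vector).

    ``init`` is normally the unpenalized estimate; with all tuning parameters
    zero the result coincides with :func:`fit_unpenalized`.
    """
    lam = effective_lambda(config, lambda_raw, data.p, data.q)
    theta0 = init.theta if init is not None else _default_init(data)
    params, obj, it, conv = _newton(data, lam, config, theta0, max_iter, tol)
    if not conv:
        logger.debug("penalized fit (lambda=%s) not converged after %d iter",
                     lambda_raw, it)
    return _finalize(data, config, lam, params, obj, it, conv)


# ---------------------------------------------------------------------------
# covariance and model complexity
# ---------------------------------------------------------------------------

def _inv_or_pinv(info: np.ndarray) -> np.ndarray:
    try:
        return linalg.inv(info)
    except linalg.LinAlgError:
        warnings.warn("singular penalized information; using pseudo-inverse")
        return linalg.pinvh(info)


def sandwich_covariance_matrices(info: np.ndarray, i0: np.ndarray) -> np.ndarray:
    """cov(theta) = I^-1 I0 I^-1, symmetrized."""
    inv = _inv_or_pinv(info)
    cov = inv @ i0 @ inv
    return (cov + cov.T) / 2.0


def sandwich_covariance(fitted: FittedModel, data: SurvivalDataset,
                        config: PenaltyConfig = _NO_PENALTY) -> np.ndarray:
    """Recompute the sandwich covariance (original scale) at the fitted value."""
    _, info, i0 = score_and_information(fitted.params_std, data,
                                        fitted.lambda_used, config)
    A = _standardization_jacobian(data)
    return A @ sandwich_covariance_matrices(info, i0) @ A.T


def effective_df_matrices(info: np.ndarray, i0: np.ndarray) -> float:
    """tr[I^-1 I0]; equals the parameter count when no penalty is active."""
    return float(np.trace(_inv_or_pinv(info) @ i0))


def effective_df(fitted: FittedModel) -> float:
    return effective_df_matrices(fitted.info_penalized, fitted.info_unpenalized)
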