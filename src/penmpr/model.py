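"""Weibull multi-parameter regression (MPR) model.

The hazard for subject *i* is ``h(t) = tau_i * gamma_i * t**(gamma_i - 1)``
with covariate-dependent scale and shape parameters entering through log
links::

    log tau_i   = x_i' beta      (scale component)
    log gamma_i = z_i' alpha     (shape component)

Both regression components carry their own design matrix (with a leading
intercept column); the two may share covariates.  This module holds the data
container, the parameter container, the log-likelihood, hazard and
hazard-ratio functions, and the Kaplan-Meier based Weibull adequacy
diagnostic (log cumulative hazard versus log time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

logger = logging.getLogger(__name__)

#: Linear predictors are clipped at +/- this value before exponentiation so
#: that intermediate Newton steps cannot overflow.  Clipping is logged.
PREDICTOR_CLIP = 50.0


_warned_clip_labels: set = set()


def _clip_predictor(eta: np.ndarray, label: str, lo=-PREDICTOR_CLIP,
                    hi=PREDICTOR_CLIP) -> np.ndarray:
    """Clip an exponent with a once-per-label warning, per-event debug log.

    Clipping mostly happens for extreme trial steps inside the line search
    (which the ascent check then rejects), so the detailed log lives at debug
    level; the first occurrence per label is surfaced as a warning.
    """
    clipped = np.clip(eta, lo, hi)
    n_clipped = int(np.sum(clipped != eta))
    if n_clipped:
        logger.debug("clipped %d %s exponent(s) into [%g, %g]",
                     n_clipped, label, lo, hi)
        if label not in _warned_clip_labels:
            _warned_clip_labels.add(label)
            logger.warning(
                "%s exponents exceed [%g, %g] and are being clipped "
                "(further events logged at debug level)", label, lo, hi,
            )
    return clipped


@dataclass
class MprParameters:
    """Regression coefficients (beta, alpha), intercepts included.

    ``beta`` has length p+1 (scale), ``alpha`` length q+1 (shape); the implied
    tau_i and gamma_i are strictly positive through the log links.
    """

    beta: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if not (np.all(np.isfinite(self.beta)) and np.all(np.isfinite(self.alpha))):
            raise ValueError("MprParameters requires finite coefficients")

    @property
    def theta(self) -> np.ndarray:
        """Stacked parameter vector (beta', alpha')'."""
        return np.concatenate([self.beta, self.alpha])

    @classmethod
    def from_theta(cls, theta: np.ndarray, n_beta: int) -> "MprParameters":
        theta = np.asarray(theta, dtype=float).ravel()
        return cls(beta=theta[:n_beta], alpha=theta[n_beta:])


@dataclass
class Standardization:
    """Per-column (mean, sd) of the non-intercept design columns."""

    mean: np.ndarray
    sd: np.ndarray


@dataclass
class SurvivalDataset:
    """Right-censored survival data with scale and shape design matrices.

    ``scale_design`` / ``shape_design`` carry a leading all-ones intercept
    column.  When built through :meth:`from_covariates` with
    ``standardize=True`` (the default, and the convention assumed by the
    penalized estimators) each non-intercept column is centred and scaled to
    unit standard deviation, and the (mean, sd) pairs are retained so that
    coefficients can be reported on the original scale.
    """

    times: np.ndarray
    events: np.ndarray
    scale_design: np.ndarray
    shape_design: np.ndarray
    scale_std: Standardization = field(default=None)
    shape_std: Standardization = field(default=None)
    scale_names: list = field(default=None)
    shape_names: list = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.events = np.asarray(self.events, dtype=float).ravel()
        self.scale_design = np.atleast_2d(np.asarray(self.scale_design, dtype=float))
        self.shape_design = np.atleast_2d(np.asarray(self.shape_design, dtype=float))
        n = self.times.shape[0]
        bad = np.nonzero(self.times <= 0)[0]
        if bad.size:
            raise ValueError(
                f"survival times must be strictly positive; offending row(s): "
                f"{bad[:5].tolist()}"
            )
        if not np.all(np.isin(self.events, (0.0, 1.0))):
            raise ValueError("event indicators must be 0 (censored) or 1 (event)")
        for name, design in (("scale", self.scale_design), ("shape", self.shape_design)):
            if design.shape[0] != n:
                raise ValueError(f"{name} design has {design.shape[0]} rows, expected {n}")
            if not np.allclose(design[:, 0], 1.0):
                raise ValueError(f"first column of the {name} design must be all ones")
        if self.events.shape[0] != n:
            raise ValueError("times and events differ in length")
        if self.scale_std is None:
            self.scale_std = Standardization(
                mean=np.zeros(self.p), sd=np.ones(self.p)
            )
        if self.shape_std is None:
            self.shape_std = Standardization(
                mean=np.zeros(self.q), sd=np.ones(self.q)
            )
        if self.scale_names is None:
            self.scale_names = [f"x{j}" for j in range(1, self.p + 1)]
        if self.shape_names is None:
            self.shape_names = [f"z{j}" for j in range(1, self.q + 1)]

    # -- shapes ---------------------------------------------------------
    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        """Number of scale covariates (excluding intercept)."""
        return self.scale_design.shape[1] - 1

    @property
    def q(self) -> int:
        """Number of shape covariates (excluding intercept)."""
        return self.shape_design.shape[1] - 1

    @classmethod
    def from_covariates(
        cls,
        times,
        events,
        scale_covariates,
        shape_covariates,
        *,
        standardize: bool = True,
        scale_names=None,
        shape_names=None,
    ) -> "SurvivalDataset":
        """Build a dataset from raw (unstandardized) covariate matrices.

        Covariate matrices must NOT contain an intercept column; one is
        prepended.  With ``standardize=True`` each covariate column is
        centred/scaled and the transformation recorded.
        """
        X = np.atleast_2d(np.asarray(scale_covariates, dtype=float))
        Z = np.atleast_2d(np.asarray(shape_covariates, dtype=float))
        if X.ndim != 2 or Z.ndim != 2:
            raise ValueError("covariate matrices must be 2-dimensional")

        def _prep(M):
            if standardize and M.shape[1] > 0:
                mean = M.mean(axis=0)
                sd = M.std(axis=0, ddof=1)
                if np.any(sd <= 0):
                    raise ValueError("constant covariate column cannot be standardized")
                Ms = (M - mean) / sd
            else:
                mean = np.zeros(M.shape[1])
                sd = np.ones(M.shape[1])
                Ms = M
            design = np.column_stack([np.ones(M.shape[0]), Ms])
            return design, Standardization(mean=mean, sd=sd)

        Xd, xstd = _prep(X)
        Zd, zstd = _prep(Z)
        return cls(
            times=times,
            events=events,
            scale_design=Xd,
            shape_design=Zd,
            scale_std=xstd,
            shape_std=zstd,
            scale_names=scale_names,
            shape_names=shape_names,
        )


def _check_dims(params: MprParameters, data: SurvivalDataset) -> None:
    if params.beta.shape[0] != data.p + 1:
        raise ValueError(
            f"beta has length {params.beta.shape[0]}, scale design expects {data.p + 1}"
        )
    if params.alpha.shape[0] != data.q + 1:
        raise ValueError(
            f"alpha has length {params.alpha.shape[0]}, shape design expects {data.q + 1}"
        )


def weibull_quantities(params: MprParameters, data: SurvivalDataset):
    """Per-subject (tau, gamma, log t, tau * t**gamma) with overflow guards.

    Also returns the clipped linear predictors (eta_scale, eta_shape).  Only
    the upper tail of the combined exponent log(tau t**gamma) needs a guard:
    a very negative exponent underflows to an exact 0 cumulative hazard.
    """
    _check_dims(params, data)
    eta_scale = _clip_predictor(data.scale_design @ params.beta, "scale")
    eta_shape = _clip_predictor(data.shape_design @ params.alpha, "shape")
    gam = np.exp(eta_shape)
    logt = np.log(data.times)
    log_mu = _clip_predictor(eta_scale + gam * logt, "cumulative-hazard",
                             lo=-np.inf)
    mu = np.exp(log_mu)
    tau = np.exp(eta_scale)
    return tau, gam, logt, mu, eta_scale, eta_shape


def log_likelihood(params: MprParameters, data: SurvivalDataset) -> float:
    """Weibull MPR log-likelihood.

    ``l0 = sum_i delta_i{log tau_i + log gamma_i + (gamma_i - 1) log t_i}
    - tau_i t_i**gamma_i``; the censored contribution is exactly
    ``log S(t_i) = -tau_i t_i**gamma_i``.
    """
    _, gam, logt, mu, eta_scale, eta_shape = weibull_quantities(params, data)
    d = data.events
    return float(np.sum(d * (eta_scale + eta_shape + (gam - 1.0) * logt) - mu))


def hazard(params: MprParameters, covs_scale, covs_shape, t) -> float:
    """Hazard ``tau * gamma * t**(gamma-1)`` at covariate rows (incl. intercept)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    x = np.asarray(covs_scale, dtype=float).ravel()
    z = np.asarray(covs_shape, dtype=float).ravel()
    tau = np.exp(float(x @ params.beta))
    gam = np.exp(float(z @ params.alpha))
    out = tau * gam * t ** (gam - 1.0)
    return float(out) if out.ndim == 0 else out


def cumulative_hazard(params: MprParameters, covs_scale, covs_shape, t):
    """``H(t) = tau * t**gamma`` for the given covariate profile."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("cumulative hazard requires t > 0")
    x = np.asarray(covs_scale, dtype=float).ravel()
    z = np.asarray(covs_shape, dtype=float).ravel()
    tau = np.exp(float(x @ params.beta))
    gam = np.exp(float(z @ params.alpha))
    return tau * t ** gam


def hazard_ratio(
    params: MprParameters,
    covariate_index: int,
    *,
    delta: float = 1.0,
    profile_shape=None,
    t=1.0,
):
    """Hazard ratio for a ``delta``-unit increment of one shared covariate.

    For a covariate appearing in both components at slope position
    ``covariate_index`` (0-based among the non-intercept covariates),

        HR(t) = exp{delta (beta_k + alpha_k)}
                * t ** [ exp(z'alpha) {exp(delta alpha_k) - 1} ]

    where ``z'`` is the representative shape profile with the incremented
    covariate held at its reference value.  If the covariate is absent from a
    component its coefficient is taken as zero (pass an index beyond that
    component's length).  When ``alpha_k = 0`` the ratio is constant in time
    and equals ``exp(delta beta_k)`` -- the familiar proportional-hazards
    ratio.

    Parameters
    ----------
    profile_shape
        Full shape design row (leading 1) fixing the remaining shape
        covariates.  Defaults to the intercept-only profile (all covariates at
        their standardized mean, i.e. zero).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard_ratio requires t > 0")
    k = covariate_index + 1  # skip intercept
    beta_k = params.beta[k] if k < params.beta.shape[0] else 0.0
    alpha_k = params.alpha[k] if k < params.alpha.shape[0] else 0.0
    if profile_shape is None:
        z = np.zeros(params.alpha.shape[0])
        z[0] = 1.0
    else:
        z = np.asarray(profile_shape, dtype=float).ravel()
    gam_ref = np.exp(float(z @ params.alpha))
    out = np.exp(delta * (beta_k + alpha_k)) * t ** (
        gam_ref * (np.exp(delta * alpha_k) - 1.0)
    )
    return float(out) if out.ndim == 0 else out


def km_log_cumhaz_points(data: SurvivalDataset) -> pd.DataFrame:
    """Weibull adequacy diagnostic: (log t, log H_hat(t)) at event times.

    H_hat(t) = -log S_KM(t) from the Kaplan-Meier estimator, with pointwise
    95% bounds obtained by transforming the Greenwood-based survival bounds.
    Under a homogeneous Weibull the points fall on a straight line with slope
    gamma and intercept log tau.  Points where the KM estimate reaches 0 or
    stays at 1 are dropped (their log cumulative hazard is undefined), so the
    terminal event of a fully observed sample is excluded.
    """
    if not np.any(data.events == 1):
        raise ValueError(
            "Weibull adequacy diagnostic needs at least one event "
            "(all-censored data has H identically 0)"
        )
    km = KaplanMeierFitter()
    km.fit(data.times, event_observed=data.events)
    event_times = np.unique(data.times[data.events == 1])
    surv = km.survival_function_at_times(event_times).to_numpy()
    ci = km.confidence_interval_survival_function_
    lo_s = np.interp(event_times, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    hi_s = np.interp(event_times, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    keep = (surv > 0.0) & (surv < 1.0)
    event_times, surv = event_times[keep], surv[keep]
    lo_s, hi_s = lo_s[keep], hi_s[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_h = np.log(-np.log(surv))
        # survival upper bound -> cumulative-hazard lower bound
        lower = np.log(-np.log(np.clip(hi_s, 1e-300, 1 - 1e-12)))
        upper = np.log(-np.log(np.clip(lo_s, 1e-300, 1 - 1e-12)))
    return pd.DataFrame(
        {
            "log_time": np.log(event_times),
            "log_cumhaz": log_h,
            "lower_95": lower,
            "upper_95": upper,
        }
    )
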