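"""Penalty families for penalized MPR estimation.

Implements the LASSO, SCAD and adaptive LASSO (ALASSO) penalties with every
occurrence of ``|theta|`` replaced by the differentiable surrogate

    a(x) = sqrt(x**2 + eps**2) - eps,   a(x) -> |x| as eps -> 0,

so the penalized objective is twice continuously differentiable and can be
maximized by Newton-Raphson.  First and second derivative companions feed the
score vector (V) and penalty curvature (Sigma) blocks of the estimation
module.  Intercepts are never penalized (their tuning-parameter slots are
identically zero).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

FAMILIES = ("lasso", "scad", "alasso")
STRUCTURES = ("single", "separate")


# ---------------------------------------------------------------------------
# smoothed absolute value
# ---------------------------------------------------------------------------

def smooth_abs(x, epsilon: float):
    """a(x) = sqrt(x^2 + eps^2) - eps; even, nonnegative, within eps of |x|."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    x = np.asarray(x, dtype=float)
    return np.sqrt(x * x + epsilon * epsilon) - epsilon


def smooth_abs_prime(x, epsilon: float):
    """a'(x) = x / sqrt(eps^2 + x^2), a smooth signum in (-1, 1)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    x = np.asarray(x, dtype=float)
    return x / np.sqrt(epsilon * epsilon + x * x)


def smooth_abs_double_prime(x, epsilon: float):
    """a''(x) = eps^2 / (eps^2 + x^2)^(3/2) > 0."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    x = np.asarray(x, dtype=float)
    return epsilon * epsilon / np.power(epsilon * epsilon + x * x, 1.5)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PenaltyConfig:
    """Penalty family, tuning-parameter structure, and smoothing constants.

    structure 'single' shares one tuning parameter lambda across the scale
    and shape components; 'separate' carries (lambda_beta, lambda_alpha).
    ALASSO requires per-coefficient adaptive weights, typically
    1/|unpenalized estimate| on the standardized scale (see
    :func:`make_adaptive_weights`); LASSO and SCAD must not carry weights.
    """

    family: str = "lasso"
    structure: str = "single"
    scad_a: float = 3.7
    epsilon: float = 1e-4
    adaptive_weights: Optional[Tuple[np.ndarray, np.ndarray]] = None
    weight_cap: float = 1e6
    zero_threshold: float = 1e-3

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown tuning structure {self.structure!r}")
        if self.scad_a <= 2:
            raise ValueError("scad_a must exceed 2")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.weight_cap <= 0:
            raise ValueError("weight_cap must be > 0")
        if self.family == "alasso":
            if self.adaptive_weights is None:
                # weights may be attached later (from the unpenalized fit)
                # via with_weights(); fitting without them is rejected.
                return
            wb, wa = self.adaptive_weights
            wb = np.asarray(wb, dtype=float)
            wa = np.asarray(wa, dtype=float)
            if np.any(wb < 0) or np.any(wa < 0):
                raise ValueError("adaptive weights must be nonnegative")
            if np.any(wb > self.weight_cap) or np.any(wa > self.weight_cap):
                raise ValueError("adaptive weights exceed weight_cap")
            self.adaptive_weights = (wb, wa)
        elif self.adaptive_weights is not None:
            raise ValueError(f"{self.family} does not take adaptive_weights")

    @property
    def n_tuning(self) -> int:
        return 1 if self.structure == "single" else 2

    def with_weights(self, w_beta, w_alpha) -> "PenaltyConfig":
        return replace(self, adaptive_weights=(np.asarray(w_beta, float),
                                               np.asarray(w_alpha, float)))


def make_adaptive_weights(unpenalized, weight_cap: float = 1e6):
    """ALASSO weights w_j = min(1/|theta0_j|, cap) from an unpenalized fit.

    ``unpenalized`` is a converged FittedModel; weights are computed from the
    standardized-scale slopes (intercepts excluded) so that weighting shares
    the penalization's scale convention.  A coefficient estimated at exactly 0
    saturates at ``weight_cap``.
    """
    if not unpenalized.converged:
        raise ValueError("adaptive weights require a converged unpenalized fit")
    if weight_cap <= 0:
        raise ValueError("weight_cap must be > 0")

    def _w(coefs):
        slopes = np.abs(np.asarray(coefs, dtype=float)[1:])
        with np.errstate(divide="ignore"):
            w = np.where(slopes > 0, 1.0 / np.where(slopes > 0, slopes, 1.0),
                         np.inf)
        return np.minimum(w, weight_cap)

    return _w(unpenalized.params_std.beta), _w(unpenalized.params_std.alpha)


def expand_lambda(structure: str, raw, p: int, q: int) -> np.ndarray:
    """Per-coefficient base tuning vector of length p+q+2, intercept slots 0."""
    raw = np.atleast_1d(np.asarray(raw, dtype=float))
    if structure == "single":
        if raw.shape[0] != 1:
            raise ValueError("structure 'single' takes one tuning parameter")
        lam_b = lam_a = raw[0]
    elif structure == "separate":
        if raw.shape[0] != 2:
            raise ValueError("structure 'separate' takes two tuning parameters")
        lam_b, lam_a = raw
    else:
        raise ValueError(f"unknown tuning structure {structure!r}")
    if lam_b < 0 or lam_a < 0:
        raise ValueError("tuning parameters must be nonnegative")
    out = np.concatenate([[0.0], np.full(p, lam_b), [0.0], np.full(q, lam_a)])
    return out


def effective_lambda(config: PenaltyConfig, raw, p: int, q: int) -> np.ndarray:
    """Expanded tuning vector with ALASSO adaptive weights folded in."""
    lam = expand_lambda(config.structure, raw, p, q)
    if config.family == "alasso":
        if config.adaptive_weights is None:
            raise ValueError(
                "alasso requires adaptive weights before fitting; compute them "
                "with make_adaptive_weights() or let the tuning driver do so"
            )
        wb, wa = config.adaptive_weights
        if wb.shape[0] != p or wa.shape[0] != q:
            raise ValueError("adaptive weight lengths do not match p, q")
        mult = np.concatenate([[0.0], wb, [0.0], wa])
        lam = lam * mult
    return lam


# ---------------------------------------------------------------------------
# penalty value and derivative companions
# ---------------------------------------------------------------------------

def _scad_pieces(u: np.ndarray, lam: np.ndarray, a: float):
    """SCAD J(u), J'(u), J''(u) as functions of u = a(theta) >= 0."""
    lam = np.broadcast_to(lam, u.shape)
    low = u <= lam
    high = u >= a * lam
    mid = ~(low | high)
    val = np.where(low, lam * u, 0.0)
    val = np.where(mid, (2 * a * lam * u - u * u - lam * lam) / (2 * (a - 1.0)), val)
    val = np.where(high, lam * lam * (a + 1.0) / 2.0, val)
    d1 = np.where(low, lam, np.where(mid, (a * lam - u) / (a - 1.0), 0.0))
    d2 = np.where(mid, -1.0 / (a - 1.0), 0.0)
    return val, d1, d2


def penalty_terms(theta, lam, config: PenaltyConfig):
    """(J, dJ/dtheta, d2J/dtheta2) in a single pass; lam per-coefficient.

    This is the hot path of the Newton iteration: one shared evaluation of
    the smoothed absolute value and its derivatives feeds the objective, the
    V vector and the Sigma diagonal simultaneously.
    """
    theta = np.asarray(theta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    eps = config.epsilon
    r = np.sqrt(theta * theta + eps * eps)
    u = r - eps
    ap = theta / r
    app = eps * eps / (r * r * r)
    if config.family in ("lasso", "alasso"):
        return lam * u, lam * ap, lam * app
    val, d1, d2 = _scad_pieces(u, lam, config.scad_a)
    return val, d1 * ap, d2 * ap * ap + d1 * app


def penalty_iteration_curvature(theta, lam, config: PenaltyConfig):
    """Secant curvature J'(theta)/theta = J'(u) / sqrt(theta^2 + eps^2).

    Shares the literal second derivative's limit at theta=0 but dominates it
    elsewhere, so a Newton iteration built on it cannot overshoot the
    smoothed kink; used only as the iteration matrix, never for df or the
    sandwich covariance.
    """
    theta = np.asarray(theta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    eps = config.epsilon
    r = np.sqrt(theta * theta + eps * eps)
    if config.family in ("lasso", "alasso"):
        return lam / r
    u = r - eps
    _, d1, _ = _scad_pieces(u, lam, config.scad_a)
    return d1 / r


def penalty_value(theta, lam, config: PenaltyConfig, weight=None):
    """J_lambda(a(theta)) elementwise; lam may be scalar or per-coefficient.

    For ALASSO, ``weight`` multiplies lam (defaults to 1 so that callers who
    pre-fold weights into lam, as the estimation module does, are unaffected).
    """
    theta = np.asarray(theta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("tuning parameters must be nonnegative")
    if weight is not None:
        lam = lam * np.asarray(weight, dtype=float)
    u = smooth_abs(theta, config.epsilon)
    if config.family in ("lasso", "alasso"):
        return lam * u
    val, _, _ = _scad_pieces(np.asarray(u), lam, config.scad_a)
    return val


def penalty_first_deriv(theta, lam, config: PenaltyConfig, weight=None):
    """dJ/dtheta = J'(u) * a'(theta) -- the V-vector entries."""
    theta = np.asarray(theta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("tuning parameters must be nonnegative")
    if weight is not None:
        lam = lam * np.asarray(weight, dtype=float)
    ap = smooth_abs_prime(theta, config.epsilon)
    if config.family in ("lasso", "alasso"):
        return lam * ap
    u = smooth_abs(theta, config.epsilon)
    _, d1, _ = _scad_pieces(np.asarray(u), lam, config.scad_a)
    return d1 * ap


def penalty_second_deriv(theta, lam, config: PenaltyConfig, weight=None):
    """d2J/dtheta2 = J''(u) a'(theta)^2 + J'(u) a''(theta) -- Sigma entries."""
    theta = np.asarray(theta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("tuning parameters must be nonnegative")
    if weight is not None:
        lam = lam * np.asarray(weight, dtype=float)
    ap = smooth_abs_prime(theta, config.epsilon)
    app = smooth_abs_double_prime(theta, config.epsilon)
    if config.family in ("lasso", "alasso"):
        return lam * app
    u = smooth_abs(theta, config.epsilon)
    _, d1, d2 = _scad_pieces(np.asarray(u), lam, config.scad_a)
    return d2 * ap * ap + d1 * app
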