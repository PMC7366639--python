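"""Bayesian decision-theoretic likelihood of stay/go choices.

A subject hears a tone at true position ``s`` on a coded stimulus axis
(-2 = punished reference, +2 = rewarded reference) and perceives ``x`` with
Gaussian noise of SD ``sigma``.  Given the percept, the posterior probability
that the tone is of the punished kind is ``Phi(-x / sigma)``.  Staying pays
``c+`` if the tone was the rewarded reference and costs ``c-`` if punished;
going pays 0.  Staying is therefore optimal when the percept exceeds the
threshold ``x* = -sigma * Phi^{-1}(alpha)`` with ``alpha = 1/(1 + C_{p/r})``.

Marginalising the percept and adding a lapse rate and linear stimulus-scale
shifts for overall bias (``delta``), previous outcome (``omega * r_prev``)
and rewarded-tone assignment (``beta * r_s``) gives the choice rule

    P_stay = (1 - lambda) * Phi((s + sigma*Phi^{-1}(alpha) + delta
                                 + omega*r_prev + beta*r_s) / sigma)
             + lambda / 2
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

from .params import ParamNatural

__all__ = [
    "alpha",
    "punishment_posterior",
    "ev_stay",
    "stay_threshold",
    "p_stay",
    "session_loglik",
    "PROB_FLOOR",
]

#: Per-trial choice probabilities are clamped to [PROB_FLOOR, 1 - PROB_FLOOR]
#: before logging so that optimisation stays finite.
PROB_FLOOR = 1e-12


def alpha(c_ratio):
    """Break-even posterior reward probability ``1 / (1 + C_{p/r})``.

    Staying is worthwhile exactly when the posterior probability of reward
    exceeds ``alpha``; heavier punisher weighting (larger ``c_ratio``)
    raises the bar.
    """
    c_ratio = np.asarray(c_ratio, dtype=float)
    if np.any(c_ratio <= 0):
        raise ValueError("c_ratio must be strictly positive")
    out = 1.0 / (1.0 + c_ratio)
    return float(out) if out.ndim == 0 else out

def punishment_posterior(x, sigma):
    """Posterior probability that the tone is punished, given percept ``x``:
    ``P(pun | x) = Phi(-x / sigma)``."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    out = ndtr(-np.asarray(x, dtype=float) / sigma)
    return float(out) if out.ndim == 0 else out


def ev_stay(x, c_plus, c_minus, sigma):
    """Expected value of staying: ``c+ (1 - P(pun|x)) - c- P(pun|x)``.
    The go response has expected value 0 by convention."""
    p_pun = punishment_posterior(x, sigma)
    out = np.asarray(c_plus, float) * (1.0 - p_pun) - np.asarray(c_minus, float) * p_pun
    return float(out) if np.ndim(out) == 0 else out


def stay_threshold(p: ParamNatural) -> float:
    """Percept above which staying is optimal: ``x* = -sigma Phi^{-1}(alpha)``."""
    return float(-p.sigma * ndtri(alpha(p.c_ratio)))


def p_stay(s, p: ParamNatural, r_prev=0.0, r_s=0.0):
    """Probability of the stay response given the true tone position.

    Parameters
    ----------
    s : array_like
        Coded tone position(s) in [-2, 2].
    p : ParamNatural
        Model parameters.
    r_prev : array_like, optional
        Previous-trial outcome code (-1 air-puff, 0 nothing, +1 sucrose).
    r_s : array_like, optional
        Rewarded-tone assignment code (+1 low tone rewarded, -1 high tone).
    """
    s = np.asarray(s, dtype=float)
    u = (
        s + p.sigma * ndtri(alpha(p.c_ratio)) + p.delta
        + p.omega * np.asarray(r_prev, float)
        + p.beta * np.asarray(r_s, float)
    ) / p.sigma
    out = (1.0 - p.lapse) * ndtr(u) + 0.5 * p.lapse
    return float(out) if out.ndim == 0 else out


def _stable_log_p(u, lapse):
    """log P_stay and log(1 - P_stay), stable for extreme ``u`` at lapse ~ 0.

    P_stay = (1-lambda) Phi(u) + lambda/2, so
    log P_stay = logaddexp(log(1-lambda) + logPhi(u), log(lambda/2)).
    """
    with np.errstate(divide="ignore"):
        log_half_lapse = np.log(0.5 * lapse) if np.ndim(lapse) == 0 else np.log(0.5 * np.asarray(lapse))
        log_one_minus = np.log1p(-np.minimum(lapse, 1.0))
    lp = np.logaddexp(log_one_minus + log_ndtr(u), log_half_lapse)
    lq = np.logaddexp(log_one_minus + log_ndtr(-u), log_half_lapse)
    return lp, lq


def session_loglik(
    s,
    choices,
    p: ParamNatural,
    r_prev=0.0,
    r_s=0.0,
) -> float:
    """Bernoulli log-likelihood of a session of stay/go choices.

    ``choices`` is 1 for stay and 0 for go (or the strings 'stay'/'go').
    Per-trial probabilities are clamped to ``[PROB_FLOOR, 1 - PROB_FLOOR]``.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    y = np.atleast_1d(np.asarray(choices))
    if y.dtype.kind in "US":
        y = (y == "stay").astype(float)
    else:
        y = y.astype(float)
    if s.shape != y.shape:
        raise ValueError("s and choices must have matching shapes")
    prob = p_stay(s, p, r_prev=r_prev, r_s=r_s)
    prob = np.clip(np.atleast_1d(prob), PROB_FLOOR, 1.0 - PROB_FLOOR)
    return float(np.sum(y * np.log(prob) + (1.0 - y) * np.log1p(-prob)))


# ---------------------------------------------------------------------------
# Vectorised internals used by the hierarchical fitter.  Parameters arrive as
# per-trial arrays on the natural scale; gradients are with respect to the
# transformed scale (delta, log C, log sigma, logit lambda, omega, beta).
# ---------------------------------------------------------------------------

_LOG_FLOOR = np.log(PROB_FLOOR)


def trial_loglik_terms(s, y, r_prev, r_s, delta, c_ratio, sigma, lapse, omega, beta):
    """Per-trial log-likelihood of the observed choice (vectorised).

    All parameter arguments broadcast against the trial arrays.
    Returns the per-trial log-probability of the realised choice, floored at
    ``log(PROB_FLOOR)``.
    """
    u = (s + sigma * ndtri(1.0 / (1.0 + c_ratio)) + delta + omega * r_prev + beta * r_s) / sigma
    # only the realised choice's branch is needed: P(choice) uses Phi(u) for
    # stay and Phi(-u) for go, so evaluate log Phi(sign * u) once
    sign = 2.0 * y - 1.0
    with np.errstate(divide="ignore"):
        log_half_lapse = np.log(0.5 * np.asarray(lapse, dtype=float))
        log_one_minus = np.log1p(-np.minimum(lapse, 1.0))
    ll = np.logaddexp(log_one_minus + log_ndtr(sign * u), log_half_lapse)
    return np.maximum(ll, _LOG_FLOOR)


def trial_loglik_and_grad(s, y, r_prev, r_s, delta, c_ratio, sigma, lapse, omega, beta):
    """Per-trial log-likelihood and its gradient on the transformed scale.

    Returns ``(ll, grad)`` where ``grad`` has shape ``(6, n_trials)`` ordered
    as (delta, log_c_ratio, log_sigma, logit_lapse, omega, beta).
    """
    a = 1.0 / (1.0 + c_ratio)
    q = ndtri(a)
    shift = delta + omega * r_prev + beta * r_s
    u = (s + shift) / sigma + q

    lp, lq = _stable_log_p(u, lapse)
    ll = np.where(y > 0.5, lp, lq)

    log_one_minus = np.log1p(-np.minimum(lapse, 1.0))
    log_phi_u = -0.5 * u * u - 0.5 * np.log(2.0 * np.pi)
    # d log P / du for the realised choice, computed as stable ratios
    # (1-lam) phi(u) / P  and  -(1-lam) phi(u) / (1-P).
    sign = np.where(y > 0.5, 1.0, -1.0)
    log_target = np.where(y > 0.5, lp, lq)
    dll_du = sign * np.exp(log_one_minus + log_phi_u - log_target)

    # phi(q) for the alpha -> threshold chain; q is finite for c_ratio > 0.
    phi_q = np.exp(-0.5 * q * q) / np.sqrt(2.0 * np.pi)

    du_ddelta = 1.0 / sigma
    du_dlogc = -(a * a) * c_ratio / phi_q
    du_dlogsig = -(s + shift) / sigma
    du_domega = r_prev / sigma
    du_dbeta = r_s / sigma

    # lapse enters outside Phi: dP/dlam = 1/2 - Phi(u) for stay, the negative
    # for go; divided by the realised-choice probability, times dlam/dlogit.
    cdf_u = ndtr(u)
    p_target = np.exp(log_target)
    dP_dlam = np.where(y > 0.5, 0.5 - cdf_u, cdf_u - 0.5)
    dll_dlogit = dP_dlam / np.maximum(p_target, PROB_FLOOR) * lapse * (1.0 - lapse)

    grad = np.stack(
        [
            dll_du * du_ddelta,
            dll_du * du_dlogc,
            dll_du * du_dlogsig,
            dll_dlogit,
            dll_du * du_domega,
            dll_du * du_dbeta,
        ]
    )
    # Where the floor is active the objective is locally flat.
    floored = ll <= _LOG_FLOOR
    ll = np.maximum(ll, _LOG_FLOOR)
    if np.any(floored):
        grad = np.where(floored[None, :], 0.0, grad)
    return ll, grad
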