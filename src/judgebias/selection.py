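"""Integrated-BIC model comparison via sampled-prior marginal likelihoods.

The integrated BIC penalises the number of fitted *top-level* parameters:

    iBIC = N_p * ln|D| - 2 * ln P(D | m, nu, Sigma)

where |D| is the total number of choices and the marginal likelihood
integrates the session parameters over the fitted empirical prior.  That
integral is estimated per session by Monte Carlo: draw ``mu ~ N(m, nu)``
then ``h ~ N(mu, Sigma)`` (``beta`` taken from the ``mu`` draw), average the
session likelihoods over K draws, and sum the logs over sessions and
subjects.  A jackknife over the K draws gives the MC standard error.

By default N_p counts 3 per session-level free parameter (its entries in
m, nu and Sigma) and 2 for beta (m and nu only); set
``count_variance_components=False`` to count only the entries of m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .choice import trial_loglik_terms
from .em import EMOptions, FitResult, SubjectData, build_subject_data, em_fit
from .params import PARAM_NAMES, HyperParams, ModelSpec, canonical_model_space

__all__ = ["IBICResult", "log_marginal_mc", "ibic", "compare_models"]


@dataclass
class IBICResult:
    spec: ModelSpec
    n_params: int
    n_data: int
    log_marginal: float
    mc_se: float
    ibic: float
    n_samples: int
    seed: int
    delta_ibic: float = float("nan")


def _subject_session_draws(data: SubjectData, hyper: HyperParams, K: int, rng):
    """Per-session log-likelihoods under K hierarchy draws, shape (N, K).

    Every session gets independent draws mu ~ N(m, nu), h ~ N(mu, Sigma)
    (beta taken from the mu draw), vectorised over the subject's sessions.
    """
    from scipy.special import expit

    spec = hyper.spec
    p = spec.n_session
    N = data.n_sessions
    mu = rng.normal(hyper.m, np.sqrt(hyper.nu), size=(N, K, spec.n_mu))
    if p:
        h = rng.normal(mu[..., :p], np.sqrt(hyper.Sigma), size=(N, K, p))
    else:
        h = np.zeros((N, K, 0))

    # unique-cell compaction: identical (session, s, r_prev, choice) trials
    # share one probability evaluation, weighted by their count
    s_u, y_u, r_u, sess_u, w_u = data.compact()
    n = s_u.size
    vals = {}
    for name in PARAM_NAMES:
        if name in spec.session_params:
            col = h[sess_u, :, spec.session_params.index(name)].T
            if name in ("c_ratio", "sigma"):
                vals[name] = np.exp(col)
            elif name == "lapse":
                vals[name] = expit(col)
            else:
                vals[name] = col
        elif name == "beta" and spec.has_beta:
            vals[name] = mu[sess_u, :, -1].T
        else:
            vals[name] = np.full((1, 1), spec.pinned[name])

    ll = trial_loglik_terms(
        s_u[None, :], y_u[None, :], r_u[None, :], float(data.r_s),
        vals["delta"], vals["c_ratio"], vals["sigma"],
        vals["lapse"], vals["omega"], vals["beta"],
    )
    onehot = np.zeros((n, N))
    onehot[np.arange(n), sess_u] = w_u
    out = (ll @ onehot).T  # (N, K)
    if out.shape[1] != K:  # fully pinned model: likelihood is draw-free
        out = np.broadcast_to(out, (N, K)).copy()
    return out


def _logmeanexp(a: np.ndarray) -> float:
    mx = np.max(a)
    return float(mx + np.log(np.mean(np.exp(a - mx))))


def log_marginal_mc(
    trials: pd.DataFrame,
    hyper: HyperParams,
    K: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Sampled-prior estimate of ln P(D | m, nu, Sigma) with jackknife SE.

    Returns ``(estimate, mc_se)``.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    rng = np.random.default_rng(seed)
    subjects = build_subject_data(trials)
    total = 0.0
    var = 0.0
    for data in subjects:
        draws = _subject_session_draws(data, hyper, K, rng)
        for ll in draws:
            lme = _logmeanexp(ll)
            total += lme
            # delete-one jackknife of log-mean-exp
            mx = np.max(ll)
            w = np.exp(ll - mx)
            sw = np.sum(w)
            loo = mx + np.log((sw - w) / (K - 1))
            var += (K - 1) / K * float(np.sum((loo - np.mean(loo)) ** 2))
    return total, float(np.sqrt(var))


def ibic(
    trials: pd.DataFrame,
    fit: FitResult,
    K: int = 2000,
    seed: int = 0,
    count_variance_components: bool = True,
) -> IBICResult:
    """Integrated BIC of a fitted model on its data."""
    spec = fit.spec
    if count_variance_components:
        n_params = spec.n_top
    else:
        n_params = spec.n_mu
    n_data = len(trials)
    lm, se = log_marginal_mc(trials, fit.hyper, K=K, seed=seed)
    return IBICResult(
        spec=spec,
        n_params=n_params,
        n_data=n_data,
        log_marginal=lm,
        mc_se=se,
        ibic=float(n_params * np.log(n_data) - 2.0 * lm),
        n_samples=K,
        seed=seed,
    )


def compare_models(
    trials: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    opts: EMOptions | None = None,
    K: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit a set of model specifications and rank them by iBIC.

    Defaults to the canonical 16-model space (every subset of
    {delta, c_ratio, sigma, lapse} joined with {omega, beta}).  All models
    see the same data and the same marginal-likelihood seed.  A failed fit
    yields a row with NaN scores rather than aborting the comparison.
    """
    specs = specs if specs is not None else canonical_model_space()
    rows = []
    for spec in specs:
        row = {
            "model_parameters": spec.label(),
            "n_params": spec.n_top,
            "n_data": len(trials),
        }
        try:
            fit = em_fit(trials, spec, opts)
            res = ibic(trials, fit, K=K, seed=seed)
            row.update(
                log_marginal=res.log_marginal,
                mc_se=res.mc_se,
                ibic=res.ibic,
                converged=fit.converged,
            )
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            row.update(
                log_marginal=np.nan, mc_se=np.nan, ibic=np.nan,
                converged=False, error=str(exc),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    table["delta_ibic"] = table["ibic"] - np.nanmin(table["ibic"])
    return table.sort_values("ibic", ignore_index=True)
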