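"""Hierarchical empirical-Bayes EM fitting of the judgement-bias model.

The generative hierarchy has four levels: top-level Gaussian ``N(m, nu)``
over subjects; per-subject means ``mu_i``; per-session parameter vectors
``h_ij ~ N(mu_i, Sigma)``; and the Bernoulli choice data.  ``nu`` and
``Sigma`` are diagonal.  The tone-assignment parameter ``beta`` is constant
within a subject, so it sits in ``mu_i`` only and has no session layer
(a three-level structure embedded in the four-level algebra).

The hyperparameters ``(m, nu, Sigma)`` are estimated by EM:

* E-step: per subject, the joint MAP of ``(mu_i, {h_ij})`` under the current
  hyperparameters, with a Laplace (inverse-Hessian) approximation of the
  joint posterior covariance; its blocks ``M00`` (subject), ``Mjj``
  (session) and ``M0j`` (cross) feed the M-step.
* M-step: moment updates — ``m`` is the mean of the subject MAPs; ``nu`` the
  mean outer-product moment (including ``M00``) minus ``m m^T``; ``Sigma``
  the pooled within-subject spread of session MAPs about each subject's
  session mean, with the Laplace covariance corrections.

Everything operates on the transformed parameter scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .params import PARAM_NAMES, HyperParams, ModelSpec
from .choice import trial_loglik_and_grad

__all__ = [
    "EMOptions",
    "SubjectData",
    "SubjectPosterior",
    "FitResult",
    "build_subject_data",
    "joint_neg_logpost",
    "estep_subject",
    "mstep",
    "em_fit",
    "pooled_map_fit",
]

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class EMOptions:
    """Tuning knobs of the EM fitter (all on the transformed scale)."""

    max_iter: int = 500
    tol: float = 1e-3  # max abs change in (m, log nu, log Sigma)
    variance_floor: float = 1e-6
    n_restarts: int = 3
    restart_jitter_sd: float = 0.5
    hessian_step: float = 1e-4
    ridge_start: float = 1e-6
    seed: int = 0
    #: if False, the between-session update omits the centring correction and
    #: measures session spread about the subject MAP instead of about the
    #: subject's session mean.
    sigma_centring_correction: bool = True
    #: Monte-Carlo monitoring of the marginal likelihood during EM: number of
    #: common-random-number samples per session (0 disables monitoring and
    #: best-iterate selection), and how many iterations without a new best
    #: before stopping.  With Laplace E-steps the EM ascent is approximate;
    #: when two parameters are nearly redundant (delta and c_ratio both shift
    #: the decision threshold) the approximation error induces a slow walk
    #: along the flat ridge that the true marginal does not support, so the
    #: fit keeps the iterate that maximises the monitored marginal.
    monitor_samples: int = 600
    monitor_patience: int = 10
    #: practical-convergence threshold: stop when the monitored marginal has
    #: improved by less than this many nats over the last ``monitor_patience``
    #: iterations.  Gains below the monitor's own resolution (the per-cohort
    #: jackknife SE at the default K is of this order) are not meaningful.
    monitor_tol: float = 0.5

    def __post_init__(self) -> None:
        for name in ("max_iter", "tol", "variance_floor", "n_restarts",
                     "restart_jitter_sd", "hessian_step", "ridge_start"):
            if not getattr(self, name) > 0:
                raise ValueError(f"EMOptions.{name} must be positive")


@dataclass
class SubjectData:
    """One subject's trials, packed as flat arrays for the likelihood core."""

    subject_id: str
    r_s: int
    s: np.ndarray
    y: np.ndarray  # 1.0 stay, 0.0 go
    r_prev: np.ndarray
    sess_idx: np.ndarray
    session_ids: list

    @property
    def n_sessions(self) -> int:
        return len(self.session_ids)

    @property
    def n_trials(self) -> int:
        return self.s.size

    def compact(self):
        """Trials collapsed to unique (session, s, r_prev, choice) cells with
        counts — an exact reduction of the Bernoulli likelihood."""
        if not hasattr(self, "_compact"):
            design = np.stack([self.sess_idx, self.s, self.r_prev, self.y])
            uniq, inv, counts = np.unique(
                design.T, axis=0, return_inverse=True, return_counts=True
            )
            self._compact = (
                uniq[:, 1],                      # s
                uniq[:, 3],                      # y
                uniq[:, 2],                      # r_prev
                uniq[:, 0].astype(np.int64),     # sess_idx
                counts.astype(float),            # weights
            )
        return self._compact


@dataclass
class SubjectPosterior:
    """Joint-MAP Laplace posterior of one subject."""

    subject_id: str
    mu_bar: np.ndarray            # (d_mu,)
    h_bars: np.ndarray            # (N, p)
    M00: np.ndarray               # (d_mu, d_mu)
    Mjj: np.ndarray               # (N, p, p)
    M0j: np.ndarray               # (N, d_mu, p)
    neg_logpost: float
    log_marginal_laplace: float
    converged: bool
    session_ids: list = field(default_factory=list)


@dataclass
class FitResult:
    """Outcome of :func:`em_fit`."""

    hyper: HyperParams
    posteriors: list
    spec: ModelSpec
    iterations: int
    converged: bool
    trace: list
    n_trials: int
    subject_ids: list

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def build_subject_data(trials: pd.DataFrame) -> list[SubjectData]:
    """Pack a tidy trial table into per-subject arrays.

    Only tone position, previous outcome, choice, tone assignment and the
    subject/session grouping are read — condition labels never enter the fit.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    out = []
    for subject_id, g in trials.groupby("subject_id", sort=True):
        session_ids = list(dict.fromkeys(g["session_id"]))
        sess_map = {sid: k for k, sid in enumerate(session_ids)}
        y = g["choice"].to_numpy()
        y = (y == "stay").astype(float) if y.dtype.kind in "OUS" else y.astype(float)
        out.append(
            SubjectData(
                subject_id=str(subject_id),
                r_s=int(g["r_s"].iloc[0]),
                s=g["s"].to_numpy(dtype=float),
                y=y,
                r_prev=g["r_prev"].to_numpy(dtype=float),
                sess_idx=g["session_id"].map(sess_map).to_numpy(dtype=np.int64),
                session_ids=session_ids,
            )
        )
    return out


# ---------------------------------------------------------------------------
# E-step objective
# ---------------------------------------------------------------------------


def _per_trial_param_arrays(spec: ModelSpec, mu, H, sess):
    """Natural-scale per-trial parameter arrays from transformed (mu, H)."""
    n = sess.size
    vals = {}
    for name in PARAM_NAMES:
        if name in spec.session_params:
            col = H[:, spec.session_params.index(name)][sess]
            if name in ("c_ratio", "sigma"):
                vals[name] = np.exp(col)
            elif name == "lapse":
                vals[name] = expit(col)
            else:
                vals[name] = col
        elif name == "beta" and spec.has_beta:
            vals[name] = np.full(n, mu[-1])
        else:
            vals[name] = np.full(n, spec.pinned[name])
    return vals


def _unpack(theta: np.ndarray, spec: ModelSpec, n_sessions: int):
    d_mu, p = spec.n_mu, spec.n_session
    mu = theta[:d_mu]
    H = theta[d_mu:].reshape(n_sessions, p)
    return mu, H


def _neg_logpost_and_grad(theta, data: SubjectData, hyper: HyperParams):
    """Negative joint log-posterior and gradient for one subject."""
    spec = hyper.spec
    N, p, d_mu = data.n_sessions, spec.n_session, spec.n_mu
    mu, H = _unpack(theta, spec, N)
    nu, Sig = hyper.nu, hyper.Sigma

    # Gaussian priors
    dm = mu - hyper.m
    lp = -0.5 * np.sum(dm * dm / nu + np.log(nu) + _LOG_2PI)
    g_mu = -dm / nu
    g_H = np.zeros((N, p))
    if N and p:
        dh = H - mu[:p]
        lp += -0.5 * np.sum(dh * dh / Sig + np.log(Sig) + _LOG_2PI)
        g_H += -dh / Sig
        g_mu[:p] += np.sum(dh / Sig, axis=0)

    # choice likelihood on the compacted (unique-cell, weighted) design
    if data.n_trials:
        s_u, y_u, r_u, sess_u, w_u = data.compact()
        vals = _per_trial_param_arrays(spec, mu, H, sess_u)
        ll, g6 = trial_loglik_and_grad(
            s_u, y_u, r_u, float(data.r_s),
            vals["delta"], vals["c_ratio"], vals["sigma"],
            vals["lapse"], vals["omega"], vals["beta"],
        )
        lp += float(np.dot(ll, w_u))
        for k, name in enumerate(spec.session_params):
            c_idx = PARAM_NAMES.index(name)
            g_H[:, k] += np.bincount(sess_u, weights=g6[c_idx] * w_u, minlength=N)
        if spec.has_beta:
            g_mu[-1] += float(np.dot(g6[5], w_u))

    grad = np.concatenate([g_mu, g_H.ravel()])
    return -lp, -grad


def joint_neg_logpost(data: SubjectData, mu, h_set, hyper: HyperParams) -> float:
    """Negative joint log-posterior at explicit (mu, {h_j}) values.

    ``h_set`` is an (N, p) array (or empty for a subject with no sessions).
    """
    spec = hyper.spec
    mu = np.asarray(mu, float).ravel()
    H = np.asarray(h_set, float).reshape(data.n_sessions, spec.n_session)
    if mu.shape != (spec.n_mu,):
        raise ValueError(f"mu must have length {spec.n_mu}")
    theta = np.concatenate([mu, H.ravel()])
    f, _ = _neg_logpost_and_grad(theta, data, hyper)
    return float(f)


def _fd_hessian(grad_fn, theta, step):
    """Central finite differences of an analytic gradient; symmetrised."""
    d = theta.size
    Hmat = np.empty((d, d))
    for k in range(d):
        e = np.zeros(d)
        e[k] = step
        gp = grad_fn(theta + e)
        gm = grad_fn(theta - e)
        Hmat[:, k] = (gp - gm) / (2.0 * step)
    return 0.5 * (Hmat + Hmat.T)


def _safe_inverse(Hmat, ridge_start, subject_id, max_ridge=1e6):
    """Invert a Hessian, escalating a ridge (x10) until positive definite."""
    d = Hmat.shape[0]
    ridge = 0.0
    while True:
        try:
            c = cho_factor(Hmat + ridge * np.eye(d))
            cov = cho_solve(c, np.eye(d))
            logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
            return cov, logdet
        except np.linalg.LinAlgError:
            ridge = ridge_start if ridge == 0.0 else ridge * 10.0
            if ridge > max_ridge:
                raise np.linalg.LinAlgError(
                    f"Hessian for subject {subject_id} not positive definite "
                    f"after maximum ridge {max_ridge:g}"
                )


def estep_subject(
    data: SubjectData,
    hyper: HyperParams,
    opts: EMOptions,
    warm_start: np.ndarray | None = None,
) -> SubjectPosterior:
    """Joint MAP of (mu_i, {h_ij}) with a Laplace covariance at the optimum.

    Starts from the prior mean plus ``n_restarts - 1`` jittered points (or a
    single warm start when one is supplied, e.g. the previous EM iteration's
    MAP); the best optimum wins, ties broken by first.
    """
    spec = hyper.spec
    N, p, d_mu = data.n_sessions, spec.n_session, spec.n_mu

    if N == 0:
        return SubjectPosterior(
            subject_id=data.subject_id,
            mu_bar=hyper.m.copy(),
            h_bars=np.zeros((0, p)),
            M00=np.diag(hyper.nu),
            Mjj=np.zeros((0, p, p)),
            M0j=np.zeros((0, d_mu, p)),
            neg_logpost=_neg_logpost_and_grad(hyper.m.copy(), data, hyper)[0],
            log_marginal_laplace=0.0,
            converged=True,
            session_ids=[],
        )

    base = np.concatenate([hyper.m, np.tile(hyper.m[:p], N)])
    if warm_start is not None:
        starts = [np.asarray(warm_start, float)]
    else:
        rng = np.random.default_rng(opts.seed)
        starts = [base] + [
            base + rng.normal(0.0, opts.restart_jitter_sd, size=base.size)
            for _ in range(max(0, opts.n_restarts - 1))
        ]

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            _neg_logpost_and_grad,
            x0,
            args=(data, hyper),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        logger.warning("E-step optimiser did not converge for subject %s",
                       data.subject_id)

    theta = best.x

    def grad_only(th):
        return _neg_logpost_and_grad(th, data, hyper)[1]

    Hmat = _fd_hessian(grad_only, theta, opts.hessian_step)
    cov, logdet = _safe_inverse(Hmat, opts.ridge_start, data.subject_id)

    mu_bar, h_bars = _unpack(theta, spec, N)
    Mjj = np.empty((N, p, p))
    M0j = np.empty((N, d_mu, p))
    for j in range(N):
        a = d_mu + j * p
        Mjj[j] = cov[a : a + p, a : a + p]
        M0j[j] = cov[:d_mu, a : a + p]
    # Laplace evidence: log \int = -f(MAP) + (d/2) log 2pi - (1/2) log det H
    d = theta.size
    log_marg = -best.fun + 0.5 * d * _LOG_2PI - 0.5 * logdet
    return SubjectPosterior(
        subject_id=data.subject_id,
        mu_bar=mu_bar.copy(),
        h_bars=h_bars.copy(),
        M00=cov[:d_mu, :d_mu],
        Mjj=Mjj,
        M0j=M0j,
        neg_logpost=float(best.fun),
        log_marginal_laplace=float(log_marg),
        converged=bool(any_success),
        session_ids=list(data.session_ids),
    )


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def mstep(
    posteriors: Sequence[SubjectPosterior],
    spec: ModelSpec,
    opts: EMOptions,
) -> HyperParams:
    """Moment updates of (m, nu, Sigma) from the subject posteriors.

    m      = mean_i mu_bar_i
    nu     = diag{ mean_i (mu_bar mu_bar^T + M00) - m m^T }
    Sigma  = diag{ pooled over sessions of
                   (h_j h_j^T - 2 h_j mu^T + mu mu^T + Mjj - 2 M0j + M00)
                   - N_i (hbar_i - mu)(hbar_i - mu)^T } / sum_i N_i
    where hbar_i is subject i's session mean and the mu/M00 factors are the
    session-level blocks.  Diagonals are floored at ``opts.variance_floor``.
    """
    if len(posteriors) == 0:
        raise ValueError("mstep requires at least one subject posterior")
    M = len(posteriors)
    p, d_mu = spec.n_session, spec.n_mu

    mus = np.stack([po.mu_bar for po in posteriors])
    m_new = mus.mean(axis=0)
    second = np.mean(
        [po.mu_bar ** 2 + np.diag(po.M00) for po in posteriors], axis=0
    )
    nu_new = np.maximum(second - m_new ** 2, opts.variance_floor)

    total_sessions = sum(po.h_bars.shape[0] for po in posteriors)
    if p == 0 or total_sessions == 0:
        Sigma_new = np.full(p, opts.variance_floor)
    else:
        acc = np.zeros(p)
        for po in posteriors:
            N = po.h_bars.shape[0]
            if N == 0:
                continue
            mu_s = po.mu_bar[:p]
            m00 = np.diag(po.M00)[:p]
            for j in range(N):
                h = po.h_bars[j]
                mjj = np.diag(po.Mjj[j])
                m0j = np.array([po.M0j[j][k, k] for k in range(p)])
                acc += h * h - 2.0 * h * mu_s + mu_s * mu_s + mjj - 2.0 * m0j + m00
            if opts.sigma_centring_correction:
                hbar = po.h_bars.mean(axis=0)
                acc -= N * (hbar - mu_s) ** 2
        Sigma_new = np.maximum(acc / total_sessions, opts.variance_floor)

    return HyperParams(spec, m_new, np.asarray(nu_new), np.asarray(Sigma_new))


# ---------------------------------------------------------------------------
# Initialisation and the EM loop
# ---------------------------------------------------------------------------


def pooled_map_fit(subjects: Sequence[SubjectData], spec: ModelSpec) -> np.ndarray:
    """A single parameter vector fitted to all trials pooled, used to seed m.

    A weak N(0, 5^2) prior on every component keeps the problem well posed
    when a parameter is barely identified in the pooled data.  When both
    ``delta`` and ``c_ratio`` are free the pooled likelihood cannot separate
    them (both only shift the decision threshold), so ``delta`` is held at
    its null of 0 here and the hierarchy is left to apportion the threshold
    between them during EM.
    """
    if "delta" in spec.free and "c_ratio" in spec.free:
        sub = ModelSpec([f for f in spec.free if f != "delta"], None)
        v = pooled_map_fit(subjects, sub)
        out = np.zeros(spec.n_mu)
        for k, nm in enumerate(sub.mu_params):
            out[spec.mu_params.index(nm)] = v[k]
        return out
    s = np.concatenate([d.s for d in subjects])
    y = np.concatenate([d.y for d in subjects])
    r_prev = np.concatenate([d.r_prev for d in subjects])
    r_s = np.concatenate([np.full(d.n_trials, float(d.r_s)) for d in subjects])
    names = spec.mu_params
    idx = [PARAM_NAMES.index(nm) for nm in names]

    def negll(v):
        full = {nm: np.full(s.size, spec.pinned[nm]) for nm in PARAM_NAMES
                if nm not in names}
        t = dict(zip(names, v))
        for nm, val in t.items():
            if nm in ("c_ratio", "sigma"):
                full[nm] = np.full(s.size, np.exp(val))
            elif nm == "lapse":
                full[nm] = np.full(s.size, expit(val))
            else:
                full[nm] = np.full(s.size, val)
        ll, g6 = trial_loglik_and_grad(
            s, y, r_prev, r_s,
            full["delta"], full["c_ratio"], full["sigma"],
            full["lapse"], full["omega"], full["beta"],
        )
        f = -np.sum(ll) + 0.5 * np.sum(v ** 2) / 25.0
        g = -np.array([np.sum(g6[i]) for i in idx]) + v / 25.0
        return f, g

    res = optimize.minimize(negll, np.zeros(len(names)), jac=True, method="L-BFGS-B")
    return res.x


def em_fit(
    trials: pd.DataFrame,
    spec: ModelSpec | None = None,
    opts: EMOptions | None = None,
) -> FitResult:
    """Fit the hierarchy to a trial table by EM.

    The fit is blind to condition labels: only subject/session grouping,
    tone position, previous outcome, tone assignment and choice are read.
    """
    spec = spec or ModelSpec.full()
    opts = opts or EMOptions()
    subjects = build_subject_data(trials)
    p = spec.n_session

    m = pooled_map_fit(subjects, spec)
    nu = np.full(spec.n_mu, 0.5)
    Sigma = np.full(p, 0.5)
    hyper = HyperParams(spec, m, nu, Sigma)

    def monitor_lm(h: HyperParams) -> float:
        # Common-random-number MC estimate of the marginal likelihood: the
        # same seed gives the same hierarchy draws, so differences between
        # iterations reflect the hyperparameters, not sampling noise.
        from .selection import _logmeanexp, _subject_session_draws

        rng = np.random.default_rng(opts.seed % (2**31 - 1))
        tot = 0.0
        for d in subjects:
            for ll in _subject_session_draws(d, h, opts.monitor_samples, rng):
                tot += _logmeanexp(ll)
        return tot

    warm: dict[str, np.ndarray] = {}
    trace = []
    converged = False
    posteriors: list[SubjectPosterior] = []
    best_lm = -np.inf
    best_hyper = hyper.copy()
    best_iter = 0
    lm_history: list[float] = []
    it = 0
    for it in range(1, opts.max_iter + 1):
        posteriors = [
            estep_subject(d, hyper, opts, warm_start=warm.get(d.subject_id))
            for d in subjects
        ]
        for d, po in zip(subjects, posteriors):
            warm[d.subject_id] = np.concatenate([po.mu_bar, po.h_bars.ravel()])
        new = mstep(posteriors, spec, opts)
        approx_lm = float(sum(po.log_marginal_laplace for po in posteriors))
        entry = {
            "iteration": it,
            "m": new.m.tolist(),
            "nu": new.nu.tolist(),
            "Sigma": new.Sigma.tolist(),
            "approx_log_marginal": approx_lm,
        }
        if opts.monitor_samples:
            mc_lm = monitor_lm(new)
            entry["mc_log_marginal"] = mc_lm
            lm_history.append(mc_lm)
            if mc_lm > best_lm:
                best_lm = mc_lm
                best_hyper = new.copy()
                best_iter = it
        trace.append(entry)
        delta = max(
            float(np.max(np.abs(new.m - hyper.m), initial=0.0)),
            float(np.max(np.abs(np.log(new.nu) - np.log(hyper.nu)), initial=0.0)),
            float(np.max(np.abs(np.log(new.Sigma) - np.log(hyper.Sigma)), initial=0.0)),
        )
        hyper = new
        if delta < opts.tol:
            converged = True
            break
        if opts.monitor_samples and it - best_iter >= opts.monitor_patience:
            converged = True
            break
        if (
            opts.monitor_samples
            and len(lm_history) > opts.monitor_patience
            and best_lm - lm_history[-1 - opts.monitor_patience] < opts.monitor_tol
        ):
            # practical convergence: gains over the last patience window are
            # below the monitor's resolution
            converged = True
            break

    if opts.monitor_samples and best_iter != it:
        # Return the iterate that maximised the monitored marginal, with a
        # final E-step pass at those hyperparameters.
        hyper = best_hyper
        posteriors = [
            estep_subject(d, hyper, opts, warm_start=warm.get(d.subject_id))
            for d in subjects
        ]

    return FitResult(
        hyper=hyper,
        posteriors=posteriors,
        spec=spec,
        iterations=it,
        converged=converged,
        trace=trace,
        n_trials=int(sum(d.n_trials for d in subjects)),
        subject_ids=[d.subject_id for d in subjects],
    )
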