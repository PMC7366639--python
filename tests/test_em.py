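"""Hierarchical EM: E-step objective/MAP oracles, M-step moment oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from judgebias.choice import session_loglik
from judgebias.em import (
    EMOptions,
    SubjectData,
    SubjectPosterior,
    _neg_logpost_and_grad,
    build_subject_data,
    em_fit,
    estep_subject,
    joint_neg_logpost,
    mstep,
)
from judgebias.params import HyperParams, ModelSpec, ParamNatural
from judgebias.simulate import GenerativeConfig, simulate_cohort


def _subject(s, y, r_prev, sess_idx, r_s=1, sid="S01"):
    sess_idx = np.asarray(sess_idx, dtype=np.int64)
    n_sess = int(sess_idx.max()) + 1 if sess_idx.size else 0
    return SubjectData(
        subject_id=sid,
        r_s=r_s,
        s=np.asarray(s, float),
        y=np.asarray(y, float),
        r_prev=np.asarray(r_prev, float),
        sess_idx=sess_idx,
        session_ids=[f"{sid}_J{k+1}" for k in range(n_sess)],
    )


class TestJointObjective:
    def test_zero_sessions_reduces_to_mu_prior(self):
        spec = ModelSpec(("delta", "beta"))
        hyper = HyperParams(spec, [0.5, -0.5], [2.0, 1.0], [3.0])
        data = _subject([], [], [], [])
        mu = np.array([1.0, 0.0])
        got = joint_neg_logpost(data, mu, np.zeros((0, 1)), hyper)
        expected = -(
            norm.logpdf(1.0, 0.5, np.sqrt(2.0)) + norm.logpdf(0.0, -0.5, 1.0)
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_hand_summed_toy(self):
        # 1 subject, 1 session, 2 trials; delta and beta free
        spec = ModelSpec(("delta", "beta"))
        hyper = HyperParams(spec, [0.0, 0.2], [0.5, 0.3], [0.4])
        data = _subject([2.0, -1.0], [1.0, 0.0], [0.0, 1.0], [0, 0], r_s=-1)
        mu = np.array([0.3, -0.1])
        h = np.array([[0.25]])
        got = joint_neg_logpost(data, mu, h, hyper)
        p = ParamNatural(delta=0.25, beta=-0.1)
        expected = -(
            norm.logpdf(0.3, 0.0, np.sqrt(0.5))
            + norm.logpdf(-0.1, 0.2, np.sqrt(0.3))
            + norm.logpdf(0.25, 0.3, np.sqrt(0.4))
            + session_loglik([2.0, -1.0], [1, 0], p, r_prev=[0.0, 1.0], r_s=-1)
        )
        assert got == pytest.approx(expected, rel=1e-10)

    def test_gradient_matches_finite_differences(self):
        spec = ModelSpec.full()
        hyper = HyperParams(spec, np.full(6, -0.2), np.full(6, 0.3), np.full(5, 0.2))
        rng = np.random.default_rng(0)
        n = 40
        data = _subject(
            rng.choice([-2.0, 0.0, 2.0], n),
            rng.integers(0, 2, n).astype(float),
            rng.choice([-1.0, 0.0, 1.0], n),
            rng.integers(0, 2, n),
        )
        theta = rng.normal(0, 0.4, 6 + 2 * 5)
        f, g = _neg_logpost_and_grad(theta, data, hyper)
        eps = 1e-6
        for k in range(theta.size):
            e = np.zeros_like(theta)
            e[k] = eps
            fd = (
                _neg_logpost_and_grad(theta + e, data, hyper)[0]
                - _neg_logpost_and_grad(theta - e, data, hyper)[0]
            ) / (2 * eps)
            assert g[k] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestEStep:
    def test_zero_sessions_returns_prior(self):
        spec = ModelSpec(("delta", "beta"))
        hyper = HyperParams(spec, [0.4, -0.2], [0.7, 0.9], [0.5])
        po = estep_subject(_subject([], [], [], []), hyper, EMOptions())
        np.testing.assert_allclose(po.mu_bar, hyper.m)
        np.testing.assert_allclose(np.diag(po.M00), hyper.nu)

    def test_map_matches_grid_search_one_param(self):
        # delta free only, one session: 2-D (mu, h) grid oracle to 1e-3
        spec = ModelSpec(("delta",))
        hyper = HyperParams(spec, [0.1], [0.2], [0.15])
        rng = np.random.default_rng(3)
        n = 30
        data = _subject(
            rng.choice([-2.0, -1.0, 0.0, 1.0, 2.0], n),
            rng.integers(0, 2, n).astype(float),
            np.zeros(n),
            np.zeros(n, dtype=int),
        )
        po = estep_subject(data, hyper, EMOptions())
        grid = np.arange(-2.0, 2.0, 1e-3)
        # profile the joint over the grid in each coordinate at the optimum
        best = (np.inf, None, None)
        coarse = np.arange(-2.0, 2.0, 0.02)
        for mu in coarse:
            vals = [
                joint_neg_logpost(data, [mu], [[h]], hyper) for h in coarse
            ]
            k = int(np.argmin(vals))
            if vals[k] < best[0]:
                best = (vals[k], mu, coarse[k])
        # refine around the coarse optimum
        mu_f = best[1] + np.arange(-0.03, 0.03, 1e-3)
        h_f = best[2] + np.arange(-0.03, 0.03, 1e-3)
        vals = np.array(
            [[joint_neg_logpost(data, [mu], [[h]], hyper) for h in h_f] for mu in mu_f]
        )
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        assert po.mu_bar[0] == pytest.approx(mu_f[i], abs=2e-3)
        assert po.h_bars[0, 0] == pytest.approx(h_f[j], abs=2e-3)

    def test_many_trials_pin_session_parameters(self):
        # 6000 trials in one session: h_bar close to the generating values
        spec = ModelSpec(("delta", "omega"))
        hyper = HyperParams(spec, [0.0, 0.0], [1.0, 1.0], [1.0, 1.0])
        rng = np.random.default_rng(12)
        true = ParamNatural(delta=-0.4, omega=0.3)
        n = 6000
        s = rng.choice([-2.0, -1.0, 0.0, 1.0, 2.0], n)
        r_prev = rng.choice([-1.0, 0.0, 1.0], n)
        from judgebias.choice import p_stay

        y = (rng.random(n) < p_stay(s, true, r_prev=r_prev, r_s=1)).astype(float)
        data = _subject(s, y, r_prev, np.zeros(n, dtype=int))
        po = estep_subject(data, hyper, EMOptions())
        assert po.h_bars[0, 0] == pytest.approx(-0.4, abs=0.1)
        assert po.h_bars[0, 1] == pytest.approx(0.3, abs=0.1)

    def test_covariance_blocks_shapes_and_symmetry(self, tiny_cohort):
        spec = ModelSpec(("sigma", "omega", "beta"))
        hyper = HyperParams(spec, [-0.2, -0.2, 0.4], [0.1, 0.1, 0.1], [0.1, 0.1])
        data = build_subject_data(tiny_cohort)[0]
        po = estep_subject(data, hyper, EMOptions())
        assert po.M00.shape == (3, 3)
        assert po.Mjj.shape == (data.n_sessions, 2, 2)
        assert po.M0j.shape == (data.n_sessions, 3, 2)
        np.testing.assert_allclose(po.M00, po.M00.T, atol=1e-10)
        assert np.all(np.diag(po.M00) >= 0)
        for j in range(data.n_sessions):
            assert np.all(np.diag(po.Mjj[j]) >= 0)


def _oracle_mstep(posteriors, p, floor, centring=True):
    """Independent plain-loop transcription of the moment updates."""
    M = len(posteriors)
    d_mu = posteriors[0].mu_bar.size
    m = np.zeros(d_mu)
    for po in posteriors:
        m += po.mu_bar
    m /= M
    nu = np.zeros(d_mu)
    for po in posteriors:
        for k in range(d_mu):
            nu[k] += po.mu_bar[k] ** 2 + po.M00[k, k]
    nu = nu / M - m**2
    total_sessions = sum(po.h_bars.shape[0] for po in posteriors)
    Sigma = np.zeros(p)
    for po in posteriors:
        N = po.h_bars.shape[0]
        hbar = po.h_bars.mean(axis=0) if N else np.zeros(p)
        for k in range(p):
            for j in range(N):
                h = po.h_bars[j, k]
                mu = po.mu_bar[k]
                Sigma[k] += (
                    h * h
                    - 2 * h * mu
                    + mu * mu
                    + po.Mjj[j][k, k]
                    - 2 * po.M0j[j][k, k]
                    + po.M00[k, k]
                )
            if centring:
                Sigma[k] -= N * (hbar[k] - po.mu_bar[k]) ** 2
    Sigma /= total_sessions
    return m, np.maximum(nu, floor), np.maximum(Sigma, floor)


def _random_posteriors(rng, M, p, d_mu, n_sessions):
    out = []
    for i in range(M):
        N = n_sessions
        A = rng.normal(size=(d_mu, d_mu))
        out.append(
            SubjectPosterior(
                subject_id=f"S{i}",
                mu_bar=rng.normal(size=d_mu),
                h_bars=rng.normal(size=(N, p)),
                M00=A @ A.T / d_mu,
                Mjj=np.stack(
                    [np.diag(rng.uniform(0.01, 1, p)) for _ in range(N)]
                ),
                M0j=rng.normal(scale=0.1, size=(N, d_mu, p)),
                neg_logpost=0.0,
                log_marginal_laplace=0.0,
                converged=True,
                session_ids=[f"S{i}_J{j}" for j in range(N)],
            )
        )
    return out


class TestMStep:
    def test_single_subject_mean(self):
        spec = ModelSpec(("delta", "beta"))
        rng = np.random.default_rng(0)
        pos = _random_posteriors(rng, 1, 1, 2, 2)
        got = mstep(pos, spec, EMOptions())
        np.testing.assert_allclose(got.m, pos[0].mu_bar)

    def test_two_subject_nu_worked_example(self):
        # scalar mu_bars 0 and 1, zero covariances: m=0.5, nu=0.25
        spec = ModelSpec(("delta",))
        pos = []
        for i, mu in enumerate([0.0, 1.0]):
            pos.append(
                SubjectPosterior(
                    subject_id=f"S{i}", mu_bar=np.array([mu]),
                    h_bars=np.array([[mu]]), M00=np.zeros((1, 1)),
                    Mjj=np.zeros((1, 1, 1)), M0j=np.zeros((1, 1, 1)),
                    neg_logpost=0.0, log_marginal_laplace=0.0, converged=True,
                    session_ids=["a"],
                )
            )
        got = mstep(pos, spec, EMOptions())
        assert got.m[0] == pytest.approx(0.5)
        assert got.nu[0] == pytest.approx(0.25)

    def test_two_session_sigma_worked_example(self):
        # h_bars 0 and 2, mu 0.5, zero covariances:
        # sum (h-mu)^2 = 0.25+2.25 = 2.5 ; centring term 2*(1-0.5)^2 = 0.5
        # Sigma = (2.5 - 0.5)/2 = 1.0
        spec = ModelSpec(("delta",))
        pos = [
            SubjectPosterior(
                subject_id="S0", mu_bar=np.array([0.5]),
                h_bars=np.array([[0.0], [2.0]]), M00=np.zeros((1, 1)),
                Mjj=np.zeros((2, 1, 1)), M0j=np.zeros((2, 1, 1)),
                neg_logpost=0.0, log_marginal_laplace=0.0, converged=True,
                session_ids=["a", "b"],
            )
        ]
        got = mstep(pos, spec, EMOptions())
        assert got.Sigma[0] == pytest.approx(1.0)

    def test_oracle_equivalence_random_inputs(self):
        # beta-bearing spec: d_mu = p + 1
        spec = ModelSpec(("delta", "c_ratio", "beta"))
        rng = np.random.default_rng(99)
        opts = EMOptions()
        for _ in range(100):
            pos = _random_posteriors(
                rng, M=rng.integers(1, 5), p=2, d_mu=3,
                n_sessions=int(rng.integers(1, 4)),
            )
            got = mstep(pos, spec, opts)
            m, nu, Sigma = _oracle_mstep(pos, 2, opts.variance_floor)
            np.testing.assert_allclose(got.m, m, atol=1e-10)
            np.testing.assert_allclose(got.nu, nu, atol=1e-10)
            np.testing.assert_allclose(got.Sigma, Sigma, atol=1e-10)

    def test_centring_correction_flag(self):
        spec = ModelSpec(("delta",))
        rng = np.random.default_rng(5)
        pos = _random_posteriors(rng, 3, 1, 1, 3)
        opts = EMOptions(sigma_centring_correction=False)
        got = mstep(pos, spec, opts)
        m, nu, Sigma = _oracle_mstep(pos, 1, opts.variance_floor, centring=False)
        np.testing.assert_allclose(got.Sigma, Sigma, atol=1e-10)

    def test_empty_raises_and_floor_applies(self):
        spec = ModelSpec(("delta",))
        with pytest.raises(ValueError):
            mstep([], spec, EMOptions())
        # one subject, one session: the centred spread is exactly zero,
        # so Sigma falls to the floor
        pos = [
            SubjectPosterior(
                subject_id="S0", mu_bar=np.array([0.3]),
                h_bars=np.array([[0.9]]), M00=np.zeros((1, 1)),
                Mjj=np.zeros((1, 1, 1)), M0j=np.zeros((1, 1, 1)),
                neg_logpost=0.0, log_marginal_laplace=0.0, converged=True,
                session_ids=["a"],
            )
        ]
        got = mstep(pos, ModelSpec(("delta",)), EMOptions())
        assert got.Sigma[0] == pytest.approx(EMOptions().variance_floor)


class TestEmFit:
    def test_small_fit_contract(self, tiny_cohort):
        spec = ModelSpec(("sigma", "omega", "beta"))
        fit = em_fit(tiny_cohort, spec, EMOptions(max_iter=30, seed=0,
                                                  monitor_samples=200))
        assert np.all(np.isfinite(fit.hyper.m))
        assert np.all(fit.hyper.nu >= EMOptions().variance_floor)
        assert np.all(fit.hyper.Sigma >= EMOptions().variance_floor)
        assert len(fit.trace) == fit.iterations
        assert fit.n_trials == len(tiny_cohort)

    def test_monitored_marginal_improves(self, tiny_cohort):
        spec = ModelSpec(("sigma", "omega", "beta"))
        fit = em_fit(tiny_cohort, spec, EMOptions(max_iter=30, seed=0,
                                                  monitor_samples=200))
        lms = [e["mc_log_marginal"] for e in fit.trace]
        assert max(lms) >= lms[0]

    def test_condition_blindness(self, tiny_cohort):
        spec = ModelSpec(("sigma", "omega", "beta"))
        opts = EMOptions(max_iter=10, seed=1, monitor_samples=100)
        fit1 = em_fit(tiny_cohort, spec, opts)
        shuffled = tiny_cohort.copy()
        rng = np.random.default_rng(0)
        label_map = {
            sid: tuple(rng.permutation(["reward", "punisher"]))
            for sid in shuffled["session_id"].unique()
        }
        shuffled["condition_valence"] = shuffled["session_id"].map(
            lambda sid: label_map[sid][0]
        )
        fit2 = em_fit(shuffled, spec, opts)
        np.testing.assert_allclose(fit2.hyper.m, fit1.hyper.m, atol=1e-12)
        np.testing.assert_allclose(fit2.hyper.nu, fit1.hyper.nu, atol=1e-12)

    def test_empty_dataset_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            em_fit(tiny_cohort.iloc[:0], ModelSpec(("omega", "beta")))
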