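"""Model/Results interface for fitting the judgement-bias choice model.

Typical use::

    from judgebias import JudgementBiasModel, GenerativeConfig, simulate_cohort

    trials = simulate_cohort(GenerativeConfig(seed=1))
    model = JudgementBiasModel(trials)          # full six-parameter model
    res = model.fit(seed=1)
    print(res.summary())
    res.contrasts()                             # condition contrast table
    res.ibic(k_samples=2000, seed=1)            # integrated BIC
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, selection
from .em import EMOptions, FitResult, em_fit
from .params import HyperParams, ModelSpec
from .simulate import validate_trials

__all__ = ["JudgementBiasModel", "JudgementBiasResults"]


class JudgementBiasModel:
    """Hierarchical Bayesian decision-theoretic model of stay/go choices.

    Parameters
    ----------
    trials : pandas.DataFrame
        Tidy trial table (one row per trial) with the standard columns
        (``subject_id``, ``session_id``, condition labels, ``r_s``,
        ``trial_index``, ``tone_khz``, ``s``, ``r_prev``, ``choice``,
        ``outcome``).
    spec : ModelSpec, optional
        Which parameters to fit; defaults to the full six-parameter model.
    validate : bool
        Check schema and task invariants on construction.
    """

    def __init__(self, trials: pd.DataFrame, spec: ModelSpec | None = None,
                 validate: bool = True):
        self.trials = validate_trials(trials) if validate else trials
        self.spec = spec or ModelSpec.full()

    @classmethod
    def from_csv(cls, path, spec: ModelSpec | None = None) -> "JudgementBiasModel":
        from .simulate import read_dataset

        return cls(read_dataset(path), spec=spec, validate=False)

    def fit(
        self,
        maxiter: int = 500,
        tol: float = 1e-3,
        seed: int = 0,
        n_restarts: int = 3,
        **options,
    ) -> "JudgementBiasResults":
        """Run the hierarchical EM fit and return a results object."""
        opts = EMOptions(max_iter=maxiter, tol=tol, seed=seed,
                         n_restarts=n_restarts, **options)
        fit = em_fit(self.trials, self.spec, opts)
        return JudgementBiasResults(self, fit)


class JudgementBiasResults:
    """Fitted hyperparameters, per-subject posteriors and diagnostics."""

    def __init__(self, model: JudgementBiasModel, fit: FitResult):
        self.model = model
        self.fit = fit

    # -- core estimates ----------------------------------------------------
    @property
    def hyperparams(self) -> HyperParams:
        return self.fit.hyper

    @property
    def params(self) -> pd.Series:
        """Top-level means m (transformed scale)."""
        return pd.Series(self.fit.hyper.m, index=self.fit.spec.transformed_labels(),
                         name="m")

    @property
    def bse(self) -> pd.Series:
        """Empirical standard error of m from the subject-level MAPs."""
        mus = np.stack([po.mu_bar for po in self.fit.posteriors])
        se = mus.std(axis=0, ddof=1) / np.sqrt(mus.shape[0])
        return pd.Series(se, index=self.fit.spec.transformed_labels(), name="bse")

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def posteriors(self):
        return self.fit.posteriors

    def subject_params(self) -> pd.DataFrame:
        """Subject-level MAPs (transformed scale), one row per subject."""
        return pd.DataFrame(
            np.stack([po.mu_bar for po in self.fit.posteriors]),
            index=self.fit.subject_ids,
            columns=self.fit.spec.transformed_labels(),
        )

    def session_params(self) -> pd.DataFrame:
        """Session-level MAPs joined to condition labels."""
        return inference.session_estimates(self.fit, self.model.trials)

    # -- model comparison and inference ------------------------------------
    def ibic(self, k_samples: int = 2000, seed: int = 0,
             **kw) -> selection.IBICResult:
        return selection.ibic(self.model.trials, self.fit, K=k_samples,
                              seed=seed, **kw)

    def condition_table(self) -> pd.DataFrame:
        return inference.condition_param_table(self.fit, self.model.trials)

    def contrasts(self, parameters=None, adjustment: str = "holm") -> pd.DataFrame:
        return inference.pairwise_contrasts(
            self.fit, self.model.trials, parameters=parameters,
            adjustment=adjustment,
        )

    def sign_flip_test(self, parameter: str, n_resamples: int = 10000,
                       seed: int = 0) -> float:
        """Sign-flip permutation test of whether the subject-level MAPs of a
        (transformed-scale) parameter have zero mean."""
        vals = self.subject_params()[parameter].to_numpy()
        return inference.sign_flip_test(vals, n_resamples=n_resamples, seed=seed)

    # -- simulation ---------------------------------------------------------
    def simulate(self, seed: int = 0) -> pd.DataFrame:
        """Posterior-predictive cohort: re-simulate every session from its
        fitted session-level MAP parameters."""
        from .simulate import simulate_session

        rng = np.random.default_rng(seed)
        spec = self.fit.spec
        trials = self.model.trials
        frames = []
        for po in self.fit.posteriors:
            sub = trials[trials["subject_id"] == po.subject_id]
            r_s = int(sub["r_s"].iloc[0])
            beta = po.mu_bar[-1] if spec.has_beta else 0.0
            for j, sess_id in enumerate(po.session_ids):
                obs = sub[sub["session_id"] == sess_id]
                p_nat = spec.natural_params(po.h_bars[j], beta=beta)
                sim = simulate_session(p_nat, obs["tone_khz"].to_numpy(), r_s, rng)
                sim.insert(0, "subject_id", po.subject_id)
                sim.insert(1, "session_id", sess_id)
                for col in ("condition_valence", "condition_specificity",
                            "condition_prevalence"):
                    sim[col] = obs[col].iloc[0]
                sim["r_s"] = r_s
                frames.append(sim)
        from .simulate import CSV_COLUMNS

        return pd.concat(frames, ignore_index=True)[CSV_COLUMNS]

    # -- presentation and persistence ---------------------------------------
    def summary(self) -> str:
        spec = self.fit.spec
        lines = [
            "Judgement-bias hierarchical model fit",
            "=" * 60,
            f"Free parameters:   {spec.label()}",
            f"Subjects:          {self.fit.n_subjects}",
            f"Trials:            {self.fit.n_trials}",
            f"EM iterations:     {self.fit.iterations}"
            f" ({'converged' if self.fit.converged else 'NOT converged'})",
            "",
            f"{'parameter':<14}{'m':>10}{'se(m)':>10}{'nu':>10}{'Sigma':>10}",
            "-" * 54,
        ]
        bse = self.bse
        labels = spec.transformed_labels()
        for i, name in enumerate(labels):
            sig = (
                f"{self.fit.hyper.Sigma[i]:>10.4f}"
                if i < spec.n_session
                else f"{'--':>10}"
            )
            lines.append(
                f"{name:<14}{self.fit.hyper.m[i]:>10.4f}{bse[name]:>10.4f}"
                f"{self.fit.hyper.nu[i]:>10.4f}{sig}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        fit = self.fit
        return {
            "spec": {"free": list(fit.spec.free), "pinned": dict(fit.spec.pinned)},
            "hyper": fit.hyper.to_dict(),
            "iterations": fit.iterations,
            "converged": fit.converged,
            "n_trials": fit.n_trials,
            "trace": fit.trace,
            "subjects": [
                {
                    "subject_id": po.subject_id,
                    "mu_bar": po.mu_bar.tolist(),
                    "mu_var": np.diag(po.M00).tolist(),
                    "sessions": [
                        {
                            "session_id": sid,
                            "h_bar": po.h_bars[j].tolist(),
                            "h_var": np.diag(po.Mjj[j]).tolist(),
                        }
                        for j, sid in enumerate(po.session_ids)
                    ],
                    "converged": po.converged,
                }
                for po in fit.posteriors
            ],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def plot_psychometric(self, ax=None):
        """Observed vs model-predicted stay proportion per tone position."""
        import matplotlib.pyplot as plt

        from .choice import p_stay

        if ax is None:
            _, ax = plt.subplots()
        trials = self.model.trials
        obs = trials.assign(stay=(trials["choice"] == "stay").astype(float))
        obs_rate = obs.groupby("s")["stay"].mean()
        spec = self.fit.spec
        pred = {}
        for po in self.fit.posteriors:
            sub = trials[trials["subject_id"] == po.subject_id]
            r_s = int(sub["r_s"].iloc[0])
            beta = po.mu_bar[-1] if spec.has_beta else 0.0
            for j in range(len(po.session_ids)):
                p_nat = spec.natural_params(po.h_bars[j], beta=beta)
                for s in (-2, -1, 0, 1, 2):
                    pred.setdefault(s, []).append(p_stay(s, p_nat, r_s=r_s))
        s_vals = sorted(pred)
        ax.plot(obs_rate.index, obs_rate.values, "o-", label="observed")
        ax.plot(s_vals, [np.mean(pred[s]) for s in s_vals], "s--",
                label="model")
        ax.set_xlabel("tone position s")
        ax.set_ylabel("P(stay)")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax
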