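"""Permutation inference and condition contrasts on fitted parameters.

The model is fitted blind to the pre-test conditions; inference about
condition effects happens *post hoc* on the session-level MAP estimates:
group the per-session estimates by condition, form within-subject paired
differences for a family of contrasts, and test them.  Group-level tests of
whether a parameter differs from zero use a two-sided sign-flip permutation
test of mean-zero symmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ContrastResult",
    "sign_flip_test",
    "condition_param_table",
    "pairwise_contrasts",
    "DEFAULT_CONTRASTS",
    "holm_adjust",
]

logger = logging.getLogger(__name__)

#: The standard 8-contrast family over the 2x2x2 condition design.  Each
#: entry maps a label to two condition groups, each a dict of fixed factor
#: levels (sessions matching the dict are averaged within subject).
DEFAULT_CONTRASTS: tuple[tuple[str, dict, dict], ...] = (
    ("task-specific vs non-specific rewards",
     {"valence": "reward", "specificity": "task-specific"},
     {"valence": "reward", "specificity": "USV"}),
    ("task-specific vs non-specific punishers",
     {"valence": "punisher", "specificity": "task-specific"},
     {"valence": "punisher", "specificity": "USV"}),
    ("non-specific rewards vs punishers",
     {"valence": "reward", "specificity": "USV"},
     {"valence": "punisher", "specificity": "USV"}),
    ("task-specific rewards vs punishers",
     {"valence": "reward", "specificity": "task-specific"},
     {"valence": "punisher", "specificity": "task-specific"}),
    ("high vs low prevalence rewards",
     {"valence": "reward", "prevalence": "high"},
     {"valence": "reward", "prevalence": "low"}),
    ("high vs low prevalence punishers",
     {"valence": "punisher", "prevalence": "high"},
     {"valence": "punisher", "prevalence": "low"}),
    ("low prevalence rewards vs punishers",
     {"valence": "reward", "prevalence": "low"},
     {"valence": "punisher", "prevalence": "low"}),
    ("high prevalence rewards vs punishers",
     {"valence": "reward", "prevalence": "high"},
     {"valence": "punisher", "prevalence": "high"}),
)


@dataclass
class ContrastResult:
    parameter: str
    contrast: str
    estimate: float
    z: float
    p_raw: float
    p_adj: float
    method: str


def sign_flip_test(
    values,
    n_resamples: int = 10000,
    seed: int = 0,
    exhaustive_threshold: int = 12,
) -> float:
    """Two-sided sign-flip permutation p-value for a zero mean.

    Randomly negates entries and recomputes the mean; p is the proportion of
    resampled means whose absolute value is >= the observed absolute mean.
    For ``n <= exhaustive_threshold`` all ``2^n`` sign patterns are
    enumerated exactly; otherwise ``n_resamples`` seeded draws are used, the
    identity pattern included, so p is always positive.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n == 0:
        raise ValueError("sign_flip_test requires at least one value")
    obs = abs(values.sum())  # |mean| comparison == |sum| comparison
    if n <= exhaustive_threshold:
        codes = np.arange(2 ** n, dtype=np.int64)
        signs = 1.0 - 2.0 * ((codes[:, None] >> np.arange(n)) & 1)
        sums = signs @ values
        return float(np.mean(np.abs(sums) >= obs - 1e-12))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, n))
    signs[0] = 1.0  # identity resample
    sums = signs @ values
    return float(np.mean(np.abs(sums) >= obs - 1e-12))


def session_estimates(fit, trials: pd.DataFrame) -> pd.DataFrame:
    """Session-level MAP estimates (transformed scale) joined to condition
    labels; one row per session, columns per fitted parameter."""
    labels = trials.drop_duplicates("session_id").set_index("session_id")[
        ["subject_id", "condition_valence", "condition_specificity",
         "condition_prevalence"]
    ]
    spec = fit.spec
    names = spec.session_params
    t_names = [spec.transformed_labels()[spec.mu_params.index(n)] for n in names]
    rows = []
    for po in fit.posteriors:
        for j, sess_id in enumerate(po.session_ids):
            row = {"session_id": sess_id, "subject_id": po.subject_id}
            for k, nm in enumerate(t_names):
                row[nm] = po.h_bars[j, k]
            if spec.has_beta:
                row["beta"] = po.mu_bar[-1]
            rows.append(row)
    est = pd.DataFrame(rows).set_index("session_id")
    missing = est.index.difference(labels.index)
    if len(missing):
        logger.warning("sessions without condition labels excluded: %s",
                       list(missing))
        est = est.drop(index=missing)
    out = est.join(labels.drop(columns="subject_id"))
    return out.rename(
        columns={
            "condition_valence": "valence",
            "condition_specificity": "specificity",
            "condition_prevalence": "prevalence",
        }
    ).reset_index()


def condition_param_table(fit, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and SE of each session-level parameter estimate.

    Grouping is post hoc — the fit itself never saw the condition labels.
    """
    est = session_estimates(fit, trials)
    factors = ["valence", "specificity", "prevalence"]
    value_cols = [c for c in est.columns
                  if c not in factors + ["session_id", "subject_id"]]
    long = est.melt(
        id_vars=factors + ["subject_id"],
        value_vars=value_cols,
        var_name="parameter",
    )
    g = long.groupby(["parameter"] + factors, observed=True)["value"]
    table = g.agg(
        mean="mean",
        se=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
        n="count",
    ).reset_index()
    return table


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    k = p.size
    adj = np.empty(k)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (k - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def pairwise_contrasts(
    fit,
    trials: pd.DataFrame,
    parameters=None,
    contrasts=DEFAULT_CONTRASTS,
    adjustment: str = "holm",
) -> pd.DataFrame:
    """Within-subject paired contrasts between condition groups.

    For each contrast, the two groups' session estimates are averaged within
    subject; the paired differences give a z statistic (mean over its
    empirical SE) and a two-sided normal p-value, adjusted across the
    contrast family per parameter (Holm by default).
    """
    if adjustment not in ("holm", "none"):
        raise ValueError("adjustment must be 'holm' or 'none'")
    est = session_estimates(fit, trials)
    factors = {"valence", "specificity", "prevalence"}
    if parameters is None:
        parameters = [c for c in est.columns
                      if c not in factors | {"session_id", "subject_id", "beta"}]
    rows = []
    for param in parameters:
        results = []
        for label, ga, gb in contrasts:
            sel_a = np.ones(len(est), dtype=bool)
            for k, v in ga.items():
                sel_a &= est[k] == v
            sel_b = np.ones(len(est), dtype=bool)
            for k, v in gb.items():
                sel_b &= est[k] == v
            a = est[sel_a].groupby("subject_id")[param].mean()
            b = est[sel_b].groupby("subject_id")[param].mean()
            common = a.index.intersection(b.index)
            if len(common) < 2:
                logger.warning("contrast %r skipped: no within-subject pairing",
                               label)
                continue
            d = (a[common] - b[common]).to_numpy()
            se = d.std(ddof=1) / np.sqrt(d.size)
            z = 0.0 if se == 0 and d.mean() == 0 else d.mean() / max(se, 1e-300)
            p_raw = float(2.0 * norm.sf(abs(z)))
            results.append((label, float(d.mean()), float(z), min(p_raw, 1.0)))
        if not results:
            continue
        p_adj = (
            holm_adjust([r[3] for r in results])
            if adjustment == "holm"
            else np.array([r[3] for r in results])
        )
        for (label, estimate, z, p_raw), pa in zip(results, p_adj):
            rows.append(
                ContrastResult(param, label, estimate, z, p_raw, float(pa),
                               adjustment)
            )
    return pd.DataFrame([r.__dict__ for r in rows])
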