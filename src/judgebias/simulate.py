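"""Synthetic judgement-bias cohorts with the study's task structure.

The emulated design: each subject completes one 60-trial test session per
pre-test condition of a 2 (valence: reward/punisher) x 2 (specificity:
task-specific/USV) x 2 (prevalence: high/low) within-subject factorial.
A session presents the two reference tones 21 times each and three ambiguous
probe tones 6 times each, in seeded random order.  Staying on the rewarded
reference yields sucrose (+1), staying on the punished reference an air-puff
(-1); probe tones are never reinforced and going always yields nothing.

Session parameters are drawn from the same Gaussian hierarchy the fitter
assumes: a subject-level vector ``mu_i ~ N(m, nu)`` and per-session vectors
``h_ij ~ N(mu_i + condition offset, Sigma)`` on the transformed scale, with
``beta`` held at its subject-level value across sessions.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .choice import p_stay
from .params import HyperParams, ModelSpec, ParamNatural

__all__ = [
    "TONES_KHZ",
    "DEFAULT_COMPOSITION",
    "CONDITIONS",
    "CSV_COLUMNS",
    "GenerativeConfig",
    "PretestSchedule",
    "default_true_hyper",
    "make_session_trials",
    "tone_to_s",
    "simulate_session",
    "simulate_cohort",
    "simulate_pretest_schedule",
    "pellet_ceiling",
    "write_dataset",
    "read_dataset",
    "validate_trials",
    "TrialTableError",
]

logger = logging.getLogger(__name__)

#: The five tones, low to high.  2 and 8 kHz are the trained references;
#: 2.8, 4 and 5.6 kHz are the untrained, never-reinforced probes (chosen to
#: be near-equidistant on a log-frequency scale).
TONES_KHZ: tuple[float, ...] = (2.0, 2.8, 4.0, 5.6, 8.0)

#: Trials per tone in a default test session (21 per reference, 6 per probe).
DEFAULT_COMPOSITION: Mapping[float, int] = {2.0: 21, 2.8: 6, 4.0: 6, 5.6: 6, 8.0: 21}

#: The eight pre-test conditions in a fixed canonical order.
CONDITIONS: tuple[tuple[str, str, str], ...] = tuple(
    (v, sp, pr)
    for v in ("reward", "punisher")
    for sp in ("task-specific", "USV")
    for pr in ("high", "low")
)

CSV_COLUMNS = [
    "subject_id",
    "session_id",
    "condition_valence",
    "condition_specificity",
    "condition_prevalence",
    "r_s",
    "trial_index",
    "tone_khz",
    "s",
    "r_prev",
    "choice",
    "outcome",
]

#: Seconds in the pre-test manipulation window, and deliveries per prevalence.
PRETEST_WINDOW_S = 900
PRETEST_DELIVERIES = {"high": 15, "low": 1}


class TrialTableError(ValueError):
    """A trial table violated the schema or a task invariant."""


def default_true_hyper() -> HyperParams:
    """Generating hyperparameters for the default synthetic cohort.

    Means (transformed scale): delta = -0.1, log C_{p/r} = -1.1,
    log sigma = -0.3, logit lambda = -3, omega = -0.2, beta = 0.5 — a cohort
    that weighs rewards above punishers (C < 1), discriminates the tones
    well, lapses on ~5% of trials, is slightly risk-averse overall and after
    favourable outcomes, and prefers the low tone.  Between-subject and
    between-session variances are 0.04 (SD 0.2) throughout.
    """
    spec = ModelSpec.full()
    m = np.array([-0.1, -1.1, -0.3, -3.0, -0.2, 0.5])
    nu = np.full(6, 0.04)
    Sigma = np.full(5, 0.04)
    return HyperParams(spec, m, nu, Sigma)


@dataclass
class GenerativeConfig:
    """Configuration of the synthetic cohort generator."""

    n_subjects: int = 14
    sessions_per_subject: int = 8
    composition: Mapping[float, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    true_hyper: HyperParams = field(default_factory=default_true_hyper)
    condition_offsets: Mapping[tuple[str, str, str], Mapping[str, float]] = field(
        default_factory=dict
    )
    seed: int = 0
    max_trials: int | None = None  # optional session truncation

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.sessions_per_subject <= 0:
            raise ValueError("n_subjects and sessions_per_subject must be positive")
        unknown = set(self.composition) - set(TONES_KHZ)
        if unknown:
            raise ValueError(f"unknown tones in composition: {sorted(unknown)}")
        if any(c < 0 for c in self.composition.values()):
            raise ValueError("composition counts must be non-negative")
        mu_names = self.true_hyper.spec.mu_params
        for cond, off in self.condition_offsets.items():
            bad = set(off) - set(mu_names)
            if bad:
                raise ValueError(
                    f"condition offset for {cond} names non-free parameters: {sorted(bad)}"
                )

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "sessions_per_subject": self.sessions_per_subject,
            "composition": {str(k): v for k, v in self.composition.items()},
            "true_hyper": self.true_hyper.to_dict(),
            "condition_offsets": {
                "|".join(k): dict(v) for k, v in self.condition_offsets.items()
            },
            "seed": self.seed,
            "max_trials": self.max_trials,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeConfig":
        return cls(
            n_subjects=d["n_subjects"],
            sessions_per_subject=d["sessions_per_subject"],
            composition={float(k): int(v) for k, v in d["composition"].items()},
            true_hyper=HyperParams.from_dict(d["true_hyper"]),
            condition_offsets={
                tuple(k.split("|")): v
                for k, v in (d.get("condition_offsets") or {}).items()
            },
            seed=d.get("seed", 0),
            max_trials=d.get("max_trials"),
        )


@dataclass(frozen=True)
class PretestSchedule:
    """Reward/punisher deliveries in the 15-minute pre-test manipulation."""

    valence: str
    specificity: str
    prevalence: str
    delivery_times: tuple[float, ...]


def simulate_pretest_schedule(condition, rng) -> PretestSchedule:
    """Draw delivery times for a pre-test manipulation: 15 deliveries under
    high prevalence, 1 under low, uniform without replacement on a 1-s grid
    within the 900-s window."""
    valence, specificity, prevalence = condition
    n = PRETEST_DELIVERIES[prevalence]
    times = np.sort(rng.choice(PRETEST_WINDOW_S, size=n, replace=False)).astype(float)
    return PretestSchedule(valence, specificity, prevalence, tuple(times))


def tone_to_s(tone_khz, r_s: int):
    """Code tones to idealised positions s in {-2,...,2}, oriented so that +2
    is the rewarded reference.  With r_s = +1 the 2 kHz tone is rewarded and
    the ordering is reversed; with r_s = -1 the 8 kHz tone is rewarded."""
    order = {t: i - 2 for i, t in enumerate(TONES_KHZ)}  # 2 kHz -> -2 ... 8 kHz -> +2
    s = np.vectorize(order.get)(np.asarray(tone_khz, float))
    return -s if r_s == 1 else s


def make_session_trials(composition: Mapping[float, int], rng) -> np.ndarray:
    """A seeded random permutation of the session's tone multiset."""
    unknown = set(composition) - set(TONES_KHZ)
    if unknown:
        raise ValueError(f"unknown tones in composition: {sorted(unknown)}")
    tones = np.repeat(
        [t for t in TONES_KHZ if t in composition],
        [composition[t] for t in TONES_KHZ if t in composition],
    ).astype(float)
    return rng.permutation(tones)


def _outcome(s: int, stay: bool) -> int:
    if not stay or abs(s) != 2:
        return 0
    return 1 if s == 2 else -1


def simulate_session(
    p: ParamNatural,
    tones: Sequence[float],
    r_s: int,
    rng,
) -> pd.DataFrame:
    """Simulate one session sequentially: each trial's stay probability uses
    the realised outcome of the previous trial (0 on the first trial)."""
    s_codes = tone_to_s(tones, r_s)
    rows = []
    r_prev = 0
    for idx, (tone, s) in enumerate(zip(tones, s_codes), start=1):
        prob = p_stay(float(s), p, r_prev=r_prev, r_s=r_s)
        stay = bool(rng.random() < prob)
        outcome = _outcome(int(s), stay)
        rows.append(
            {
                "trial_index": idx,
                "tone_khz": float(tone),
                "s": int(s),
                "r_prev": int(r_prev),
                "choice": "stay" if stay else "go",
                "outcome": outcome,
            }
        )
        r_prev = outcome
    return pd.DataFrame(rows)


def simulate_cohort(cfg: GenerativeConfig) -> pd.DataFrame:
    """Simulate a full cohort as a tidy trial table (one row per trial).

    Per subject: draw ``mu_i ~ N(m, nu)``; per session, draw the session
    block ``h_ij ~ N(mu_i[:p] + offset, Sigma)`` and keep ``beta`` from
    ``mu_i``; simulate choices trial by trial.  The rewarded-tone assignment
    r_s is +1 for the first half of the subjects and -1 for the rest.
    Session-to-condition assignment cycles the canonical condition order.
    """
    rng = np.random.default_rng(cfg.seed)
    hyper = cfg.true_hyper
    spec = hyper.spec
    p_sess = spec.n_session
    frames = []
    for i in range(cfg.n_subjects):
        subject_id = f"S{i + 1:02d}"
        r_s = 1 if i < (cfg.n_subjects + 1) // 2 else -1
        mu = rng.normal(hyper.m, np.sqrt(hyper.nu))
        beta_val = mu[-1] if spec.has_beta else 0.0
        for j in range(cfg.sessions_per_subject):
            condition = CONDITIONS[j % len(CONDITIONS)]
            offset = np.zeros(p_sess)
            off_map = cfg.condition_offsets.get(condition, {})
            for name, val in off_map.items():
                if name in spec.session_params:
                    offset[spec.session_params.index(name)] += val
            h = rng.normal(mu[:p_sess] + offset, np.sqrt(hyper.Sigma))
            params = spec.natural_params(h, beta=beta_val)
            tones = make_session_trials(cfg.composition, rng)
            if cfg.max_trials is not None:
                tones = tones[: cfg.max_trials]
            sess = simulate_session(params, tones, r_s, rng)
            sess.insert(0, "subject_id", subject_id)
            sess.insert(1, "session_id", f"{subject_id}_J{j + 1}")
            sess.insert(2, "condition_valence", condition[0])
            sess.insert(3, "condition_specificity", condition[1])
            sess.insert(4, "condition_prevalence", condition[2])
            sess.insert(5, "r_s", r_s)
            frames.append(sess)
    return pd.concat(frames, ignore_index=True)[CSV_COLUMNS]


def pellet_ceiling(schedule: PretestSchedule, session: pd.DataFrame) -> int:
    """Maximum sucrose pellets obtainable from one pre-test manipulation plus
    one test session: pre-test deliveries count only when they are sucrose
    (reward valence, task-specific), and the session contributes one pellet
    per rewarded-reference trial (assuming the agent always stays on them).
    """
    pretest = (
        len(schedule.delivery_times)
        if (schedule.valence == "reward" and schedule.specificity == "task-specific")
        else 0
    )
    return int(pretest + int((session["s"] == 2).sum()))


# ---------------------------------------------------------------------------
# Trial-table I/O and validation
# ---------------------------------------------------------------------------


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check schema and task invariants of a trial table; return it typed.

    Raises :class:`TrialTableError` naming the first offending row.
    """
    missing = [c for c in CSV_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialTableError(f"missing columns: {missing}")
    if len(trials) == 0:
        warnings.warn("empty trial table", stacklevel=2)
        return trials.copy()
    t = trials.copy()
    for col in ("r_s", "trial_index", "s", "r_prev", "outcome"):
        t[col] = t[col].astype(int)
    t["tone_khz"] = t["tone_khz"].astype(float)

    def _fail(mask: pd.Series, msg: str) -> None:
        if mask.any():
            row = int(mask.idxmax())
            raise TrialTableError(f"row {row}: {msg}")

    _fail(~t["s"].isin([-2, -1, 0, 1, 2]), "s outside {-2..2}")
    _fail(~t["r_prev"].isin([-1, 0, 1]), "r_prev outside {-1,0,1}")
    _fail(~t["outcome"].isin([-1, 0, 1]), "outcome outside {-1,0,1}")
    _fail(~t["choice"].isin(["stay", "go"]), "choice not 'stay'/'go'")
    _fail(~t["r_s"].isin([-1, 1]), "r_s outside {-1,+1}")
    _fail(~t["tone_khz"].isin(TONES_KHZ), "unknown tone")
    _fail((t["choice"] == "go") & (t["outcome"] != 0), "go trial with an outcome")
    _fail(t["s"].abs().ne(2) & (t["outcome"] != 0), "reinforced probe tone")
    _fail((t["s"] == 2) & (t["choice"] == "stay") & (t["outcome"] != 1),
          "stay on rewarded reference without sucrose")
    _fail((t["s"] == -2) & (t["choice"] == "stay") & (t["outcome"] != -1),
          "stay on punished reference without air-puff")

    for sess_id, g in t.groupby("session_id", sort=False):
        g = g.sort_values("trial_index")
        expected = np.concatenate([[0], g["outcome"].to_numpy()[:-1]])
        bad = g["r_prev"].to_numpy() != expected
        if bad.any():
            row = int(g.index[np.argmax(bad)])
            raise TrialTableError(
                f"row {row}: r_prev inconsistent with previous outcome in session {sess_id}"
            )
        if g["r_s"].nunique() != 1:
            raise TrialTableError(f"session {sess_id}: r_s not constant")
    for subj, g in t.groupby("subject_id", sort=False):
        if g["r_s"].nunique() != 1:
            raise TrialTableError(f"subject {subj}: r_s not constant")
    return t


def write_dataset(trials: pd.DataFrame, path, config: GenerativeConfig | None = None) -> None:
    """Write a trial table as UTF-8 CSV (plus a JSON config sidecar if given)."""
    path = Path(path)
    trials.to_csv(path, index=False, lineterminator="\n")
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".config.json")
        sidecar.write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    try:
        trials = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise TrialTableError(f"{path}: empty or malformed CSV") from e
    if len(trials) == 0:
        logger.warning("empty trial table read from %s", path)
    return validate_trials(trials)
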