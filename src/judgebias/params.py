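"""Parameter containers and transforms for the judgement-bias decision model.

The model has six behavioural parameters:

``delta``
    Additive bias toward the risky "stay" response, on the stimulus scale.
``c_ratio``
    :math:`C_{p/r} = c^-/c^+`, the subjective value of the punisher relative
    to the reward.  Values above 1 mean punishers weigh more than rewards.
``sigma``
    Perceptual noise standard deviation on the stimulus scale (inverse
    psychometric slope).
``lapse``
    Stimulus-independent error rate :math:`\\lambda`; a lapse splits the
    choice 50/50.
``omega``
    Stimulus-scale shift per unit of the previous trial's outcome
    (coded -1 air-puff, 0 nothing, +1 sucrose).
``beta``
    Stimulus-scale shift per unit of the rewarded-tone assignment code
    (+1 when the low tone is rewarded, -1 when the high tone is).

For Gaussian hierarchical fitting, ``c_ratio`` and ``sigma`` are log
transformed and ``lapse`` is logit transformed; ``delta``, ``omega`` and
``beta`` are left on their natural scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "PARAM_NAMES",
    "TRANSFORMED_NAMES",
    "SESSION_PARAMS",
    "PINNED_DEFAULTS",
    "ParamNatural",
    "ParamTransformed",
    "ModelSpec",
    "HyperParams",
    "canonical_model_space",
]

#: Canonical parameter order used for every vector quantity in the package.
PARAM_NAMES: tuple[str, ...] = ("delta", "c_ratio", "sigma", "lapse", "omega", "beta")

#: Transformed-scale names, index-aligned with :data:`PARAM_NAMES`.
TRANSFORMED_NAMES: tuple[str, ...] = (
    "delta",
    "log_c_ratio",
    "log_sigma",
    "logit_lapse",
    "omega",
    "beta",
)

#: Parameters that may vary between sessions; ``beta`` is subject-level only.
SESSION_PARAMS: tuple[str, ...] = ("delta", "c_ratio", "sigma", "lapse", "omega")

#: Natural-scale values used for parameters a model pins (does not fit).
PINNED_DEFAULTS: Mapping[str, float] = {
    "delta": 0.0,
    "c_ratio": 1.0,
    "sigma": 1.0,
    "lapse": 0.0,
    "omega": 0.0,
    "beta": 0.0,
}


def _positive(name: str, value: float) -> float:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class ParamNatural:
    """Model parameters on their natural scale."""

    delta: float = 0.0
    c_ratio: float = 1.0
    sigma: float = 1.0
    lapse: float = 0.0
    omega: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        _positive("c_ratio", self.c_ratio)
        _positive("sigma", self.sigma)
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must lie in [0, 1], got {self.lapse!r}")

    def to_transformed(self, *, allow_boundary: bool = False) -> "ParamTransformed":
        """Map to the unconstrained fitting scale.

        ``lapse`` values of exactly 0 or 1 have no finite logit; they raise
        unless ``allow_boundary`` is set, in which case they map to -/+inf.
        """
        if self.lapse in (0.0, 1.0) and not allow_boundary:
            raise ValueError(
                "lapse on the boundary {0, 1} has no finite logit; "
                "pass allow_boundary=True to map it to +/-inf"
            )
        return ParamTransformed(
            delta=self.delta,
            log_c_ratio=float(np.log(self.c_ratio)),
            log_sigma=float(np.log(self.sigma)),
            logit_lapse=float(logit(self.lapse)),
            omega=self.omega,
            beta=self.beta,
        )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)


@dataclass(frozen=True)
class ParamTransformed:
    """Model parameters on the unconstrained (Gaussian-hierarchy) scale."""

    delta: float = 0.0
    log_c_ratio: float = 0.0
    log_sigma: float = 0.0
    logit_lapse: float = float("-inf")
    omega: float = 0.0
    beta: float = 0.0

    def to_natural(self) -> ParamNatural:
        return ParamNatural(
            delta=self.delta,
            c_ratio=float(np.exp(self.log_c_ratio)),
            sigma=float(np.exp(self.log_sigma)),
            lapse=float(expit(self.logit_lapse)),
            omega=self.omega,
            beta=self.beta,
        )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in TRANSFORMED_NAMES], dtype=float)


def to_transformed(p: ParamNatural, **kw) -> ParamTransformed:
    """Functional alias for :meth:`ParamNatural.to_transformed`."""
    return p.to_transformed(**kw)


def to_natural(p: ParamTransformed) -> ParamNatural:
    """Functional alias for :meth:`ParamTransformed.to_natural`."""
    return p.to_natural()


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters a model fits, and pinned values for the rest.

    ``free`` is stored in canonical order.  The session-level block is the
    free intersection with :data:`SESSION_PARAMS`; ``beta``, when free, lives
    only at the subject level (it cannot vary within a subject because the
    rewarded-tone assignment does not).
    """

    free: tuple[str, ...]
    pinned: Mapping[str, float] = field(default_factory=dict)

    def __init__(self, free: Iterable[str], pinned: Mapping[str, float] | None = None):
        free = tuple(sorted(set(free), key=PARAM_NAMES.index))
        unknown = set(free) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        pinned_full = dict(PINNED_DEFAULTS)
        if pinned:
            bad = set(pinned) & set(free)
            if bad:
                raise ValueError(f"cannot pin free parameters: {sorted(bad)}")
            pinned_full.update(pinned)
        pinned_full = {k: float(v) for k, v in pinned_full.items() if k not in free}
        object.__setattr__(self, "free", free)
        object.__setattr__(self, "pinned", pinned_full)

    @classmethod
    def full(cls) -> "ModelSpec":
        return cls(PARAM_NAMES)

    @classmethod
    def from_string(cls, text: str) -> "ModelSpec":
        """Parse a comma-separated list such as ``"c_ratio,sigma,lapse,omega,beta"``."""
        names = [t.strip() for t in text.split(",") if t.strip()]
        return cls(names)

    @property
    def session_params(self) -> tuple[str, ...]:
        return tuple(p for p in self.free if p in SESSION_PARAMS)

    @property
    def has_beta(self) -> bool:
        return "beta" in self.free

    @property
    def mu_params(self) -> tuple[str, ...]:
        """Subject-level vector layout: session params then beta."""
        return self.session_params + (("beta",) if self.has_beta else ())

    @property
    def n_session(self) -> int:
        return len(self.session_params)

    @property
    def n_mu(self) -> int:
        return len(self.mu_params)

    @property
    def n_top(self) -> int:
        """Number of fitted top-level parameters: mean, between-subject and
        between-session variance per session parameter (3 each); mean and
        between-subject variance for beta (2)."""
        return 3 * self.n_session + (2 if self.has_beta else 0)

    def label(self) -> str:
        return ",".join(self.free)

    def transformed_labels(self) -> tuple[str, ...]:
        return tuple(TRANSFORMED_NAMES[PARAM_NAMES.index(p)] for p in self.mu_params)

    def natural_params(
        self, session_values: np.ndarray, beta: float = 0.0
    ) -> ParamNatural:
        """Build a full natural parameter set from a transformed session-level
        vector plus the subject-level beta (transformed == natural for beta)."""
        full = {k: v for k, v in self.pinned.items()}
        t = dict(zip(self.session_params, np.asarray(session_values, float)))
        if "delta" in t:
            full["delta"] = t["delta"]
        if "c_ratio" in t:
            full["c_ratio"] = float(np.exp(t["c_ratio"]))
        if "sigma" in t:
            full["sigma"] = float(np.exp(t["sigma"]))
        if "lapse" in t:
            full["lapse"] = float(expit(t["lapse"]))
        if "omega" in t:
            full["omega"] = t["omega"]
        if self.has_beta:
            full["beta"] = float(beta)
        return ParamNatural(**full)


def canonical_model_space() -> list[ModelSpec]:
    """The 16-model comparison space: every subset of
    {delta, c_ratio, sigma, lapse}, each combined with {omega, beta}."""
    optional = ("delta", "c_ratio", "sigma", "lapse")
    specs = []
    for r in range(len(optional) + 1):
        for combo in itertools.combinations(optional, r):
            specs.append(ModelSpec(combo + ("omega", "beta")))
    return specs


@dataclass
class HyperParams:
    """Top-level hyperparameters of the Gaussian hierarchy.

    ``m`` and ``nu`` are the mean and (diagonal) between-subject variance of
    the subject-level vector (layout :attr:`ModelSpec.mu_params`); ``Sigma``
    is the diagonal between-session variance over the session-level block
    only — beta has no session layer.
    All on the transformed scale.
    """

    spec: ModelSpec
    m: np.ndarray
    nu: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.atleast_1d(np.asarray(self.m, dtype=float))
        self.nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        self.Sigma = np.atleast_1d(np.asarray(self.Sigma, dtype=float))
        if self.m.shape != (self.spec.n_mu,) or self.nu.shape != (self.spec.n_mu,):
            raise ValueError(
                f"m and nu must have length {self.spec.n_mu} "
                f"(mu layout {self.spec.mu_params})"
            )
        if self.Sigma.shape != (self.spec.n_session,):
            raise ValueError(
                f"Sigma must have length {self.spec.n_session} "
                f"(session layout {self.spec.session_params})"
            )
        if np.any(self.nu < 0) or np.any(self.Sigma < 0):
            raise ValueError("variance components must be non-negative")

    def copy(self) -> "HyperParams":
        return HyperParams(self.spec, self.m.copy(), self.nu.copy(), self.Sigma.copy())

    def to_dict(self) -> dict:
        return {
            "free": list(self.spec.free),
            "pinned": dict(self.spec.pinned),
            "m": self.m.tolist(),
            "nu": self.nu.tolist(),
            "Sigma": self.Sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        spec = ModelSpec(d["free"], d.get("pinned") or None)
        return cls(spec, np.array(d["m"]), np.array(d["nu"]), np.array(d["Sigma"]))
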