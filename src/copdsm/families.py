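"""Parametric transition-time families and the covariate/frailty link.

Four classical sojourn-time distributions drive the two-state model of COPD
exacerbations: exponential (constant hazard, the Markov case), Weibull
(power-law hazard), Gompertz (exponential-in-time hazard, shape may be
negative, giving a defective distribution) and log-logistic (unimodal hazard).
Each exposes hazard ``h(t)``, survival ``S(t)``, density ``f = h * S`` and the
quantile function, in the rate-style parameterisation used throughout:

* exponential:  ``h = theta``,                ``S = exp(-theta t)``
* Weibull:      ``h = theta alpha t^(a-1)``,  ``S = exp(-theta t^alpha)``
* Gompertz:     ``h = theta exp(alpha t)``,   ``S = exp((theta/alpha)(1 - e^{alpha t}))``
* log-logistic: ``h = alpha (t/theta)^alpha / (t (1 + (t/theta)^alpha))``,
                ``S = 1 / (1 + (t/theta)^alpha)``

``theta`` is the scale (``> 0``; for the log-logistic it is the median sojourn
time in days, for the others a rate-like quantity per day^alpha) and ``alpha``
the shape. Subject-level heterogeneity enters through a log-linear link on the
scale: ``theta_kj = theta0 * exp(eta_j) * exp(beta_0 log T_j + sum_w beta_w x_jw)``
with a normal frailty ``eta_j ~ N(0, sigma^2)`` exponentiated so the scale
stays positive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "Family",
    "TransitionSpec",
    "SubjectCovariates",
    "hazard",
    "survival",
    "density",
    "log_hazard",
    "log_survival",
    "quantile",
    "link_subject_params",
    "COVARIATE_FIELDS",
]

# Below this |alpha| the Gompertz survival (theta/alpha)(1 - e^{alpha t}) is
# evaluated as its exponential limit -theta*t to avoid 0/0.
_GOMPERTZ_EPS = 1e-12


class Family(str, enum.Enum):
    """The four sojourn-time distribution families."""

    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    GOMPERTZ = "gompertz"
    LOGLOGISTIC = "loglogistic"

    @property
    def has_shape(self) -> bool:
        return self is not Family.EXPONENTIAL


def _validate(family: Family, theta, alpha, t=None, *, t_positive: bool) -> None:
    family = Family(family)
    if np.any(np.asarray(theta) <= 0):
        raise ValueError(f"theta must be > 0 for {family.value}, got {theta}")
    if family.has_shape:
        if alpha is None:
            raise ValueError(f"alpha is required for the {family.value} family")
        if family in (Family.WEIBULL, Family.LOGLOGISTIC) and np.any(
            np.asarray(alpha) <= 0
        ):
            raise ValueError(f"alpha must be > 0 for {family.value}, got {alpha}")
    if t is not None:
        t = np.asarray(t)
        if t_positive and np.any(t <= 0):
            raise ValueError(f"t must be > 0, got {t}")
        if not t_positive and np.any(t < 0):
            raise ValueError(f"t must be >= 0, got {t}")


def log_hazard(family: Family, t, theta, alpha=None):
    """log h(t); vectorised over ``t``, ``theta``, ``alpha``."""
    _validate(family, theta, alpha, t, t_positive=True)
    family = Family(family)
    t = np.asarray(t, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if family is Family.EXPONENTIAL:
        return np.broadcast_to(np.log(theta), np.broadcast_shapes(t.shape, theta.shape)).copy()
    alpha = np.asarray(alpha, dtype=float)
    if family is Family.WEIBULL:
        return np.log(theta) + np.log(alpha) + (alpha - 1.0) * np.log(t)
    if family is Family.GOMPERTZ:
        return np.log(theta) + alpha * t
    # log-logistic: log alpha + alpha*log(t/theta) - log t - log(1 + (t/theta)^alpha)
    z = alpha * (np.log(t) - np.log(theta))
    return np.log(alpha) + z - np.log(t) - np.logaddexp(0.0, z)


def log_survival(family: Family, t, theta, alpha=None):
    """log S(t); defined for t >= 0, with S(0) = 1."""
    _validate(family, theta, alpha, t, t_positive=False)
    family = Family(family)
    t = np.asarray(t, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if family is Family.EXPONENTIAL:
        return -theta * t
    alpha = np.asarray(alpha, dtype=float)
    if family is Family.WEIBULL:
        return -theta * np.power(t, alpha)
    if family is Family.GOMPERTZ:
        # -(theta/alpha) * expm1(alpha t); expm1 keeps small alpha*t accurate,
        # exact exponential limit taken at |alpha| below machine-level
        small = np.abs(alpha) < _GOMPERTZ_EPS
        out = np.where(
            small,
            -theta * t,
            -(theta / np.where(small, 1.0, alpha)) * np.expm1(alpha * t),
        )
        return out
    with np.errstate(divide="ignore"):
        z = alpha * (np.log(t) - np.log(theta))  # t=0 -> z=-inf -> logS=0
    return -np.logaddexp(0.0, z)


def hazard(family: Family, t, theta, alpha=None):
    """Instantaneous transition rate h(t) per day, t > 0."""
    return np.exp(log_hazard(family, t, theta, alpha))


def survival(family: Family, t, theta, alpha=None):
    """Survival S(t) = P(sojourn > t), t >= 0."""
    return np.exp(log_survival(family, t, theta, alpha))


def density(family: Family, t, theta, alpha=None):
    """Density f(t) = h(t) * S(t), t > 0."""
    return np.exp(log_hazard(family, t, theta, alpha) + log_survival(family, t, theta, alpha))


def quantile(family: Family, u, theta, alpha=None):
    """Inverse CDF: the t with 1 - S(t) = u, for u in (0, 1).

    For a Gompertz with negative shape the distribution is defective
    (``S(inf) = exp(theta/alpha) > 0``); quantiles beyond the available mass
    are ``inf``, which the simulator treats as "no transition before the end
    of follow-up".
    """
    _validate(family, theta, alpha, None, t_positive=True)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError(f"u must lie strictly inside (0, 1), got {u}")
    family = Family(family)
    theta = np.asarray(theta, dtype=float)
    if family is Family.EXPONENTIAL:
        return -np.log1p(-u) / theta
    alpha = np.asarray(alpha, dtype=float)
    if family is Family.WEIBULL:
        return np.power(-np.log1p(-u) / theta, 1.0 / alpha)
    if family is Family.GOMPERTZ:
        small = np.abs(alpha) < _GOMPERTZ_EPS
        safe_alpha = np.where(small, 1.0, alpha)
        arg = 1.0 - (safe_alpha / theta) * np.log1p(-u)
        with np.errstate(invalid="ignore", divide="ignore"):
            gomp = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / safe_alpha, np.inf)
        return np.where(small, -np.log1p(-u) / theta, gomp)
    return theta * np.power(u / (1.0 - u), 1.0 / alpha)


COVARIATE_FIELDS = ("treatment", "disease_stage", "smoke", "pack_years", "season")


@dataclass(frozen=True)
class SubjectCovariates:
    """Baseline covariates for one trial subject.

    ``treatment``: 1 = active arm; ``disease_stage``: 1 = moderate or worse;
    ``smoke``: 1 = current smoker; ``pack_years``: cumulative cigarette packs
    per year (continuous); ``season``: 1 = enrolled spring-summer;
    ``study_length``: nominal follow-up T_j in days.
    """

    treatment: int = 0
    disease_stage: int = 0
    smoke: int = 0
    pack_years: float = 0.0
    season: int = 0
    study_length: float = 364.0

    def __post_init__(self):
        for name in ("treatment", "disease_stage", "smoke", "season"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {getattr(self, name)}")
        if self.pack_years < 0:
            raise ValueError("pack_years must be >= 0")
        if self.study_length <= 0:
            raise ValueError("study_length must be > 0")


@dataclass
class TransitionSpec:
    """Family plus fixed effects, covariate coefficients and frailty variance
    for one transition direction.

    ``beta`` maps covariate names to coefficients; the reserved key
    ``"log_study_length"`` is the coefficient on log T_j and is always part of
    the linear predictor. ``sigma2`` is the variance of the subject frailty
    eta (log-normal multiplier on the scale).
    """

    state_from: int
    family: Family
    theta0: float
    alpha: float | None = None
    beta: dict = field(default_factory=dict)
    sigma2: float = 0.0

    def __post_init__(self):
        self.family = Family(self.family)
        if self.state_from not in (1, 2):
            raise ValueError("state_from must be 1 or 2")
        if self.theta0 <= 0:
            raise ValueError("theta0 must be > 0")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.family.has_shape and self.alpha is None:
            raise ValueError(f"{self.family.value} requires a shape alpha")
        if self.family in (Family.WEIBULL, Family.LOGLOGISTIC) and self.alpha is not None:
            if self.alpha <= 0:
                raise ValueError(f"alpha must be > 0 for {self.family.value}")
        bad = set(self.beta) - set(COVARIATE_FIELDS) - {"log_study_length"}
        if bad:
            raise ValueError(f"unknown covariates in beta: {sorted(bad)}")

    @property
    def state_to(self) -> int:
        return 3 - self.state_from


def link_subject_params(
    spec: TransitionSpec, cov: SubjectCovariates, eta: float = 0.0
) -> tuple[float, float | None]:
    """Map a subject's covariates and frailty draw to per-subject parameters.

    theta_kj = theta0 * exp(eta) * exp(beta_0 log T_j + sum_w beta_w x_w);
    the shape is passed through unchanged (frailty acts on the scale only).
    """
    lp = float(eta)
    for name, coef in spec.beta.items():
        if name == "log_study_length":
            lp += coef * math.log(cov.study_length)
        else:
            lp += coef * float(getattr(cov, name))
    theta_kj = spec.theta0 * math.exp(lp)
    return theta_kj, spec.alpha
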