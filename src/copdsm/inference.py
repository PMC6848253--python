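"""Bayesian inference for the two-state semi-Markov exacerbation model.

The joint likelihood is a product over sojourns: a completed sojourn of
length ``t`` contributes ``h(t) S(t)`` and a right-censored one ``S(t)``,
with per-subject scale parameters obtained from the log-linear
covariate/frailty link. Vague priors follow the original analysis —
normal(0, 1000) on coefficients and on the unconstrained (log-transformed)
scale/shape parameters, and gamma(0.001, 0.001) on the frailty precision
``tau = 1/sigma^2``.

Sampling is Metropolis-within-Gibbs, tailored to the model's structure:

* adaptive random-walk Metropolis blocks on the unconstrained global
  parameters of each transition direction (and of the dropout submodel when
  attached), with the proposal covariance learned during warmup;
* a vectorised per-subject Metropolis update for the frailties, valid because
  subjects are conditionally independent given the global parameters;
* a conjugate Gibbs draw for the frailty precision.

Model fit is summarised by the deviance information criterion
``DIC = Dbar + pD`` with ``pD = Dbar - D(posterior means)``, using the
conditional deviance ``-2 log p(data | globals, frailties)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialDataset
from .families import (
    COVARIATE_FIELDS,
    Family,
    TransitionSpec,
    log_hazard,
    log_survival,
)

__all__ = [
    "ModelFormula",
    "PriorConfig",
    "SamplerConfig",
    "PosteriorFit",
    "sojourn_loglik",
    "total_loglik",
    "fit",
    "dic",
    "significant",
    "DIRECTIONS",
]

DIRECTIONS = ("1->2", "2->1")
_DIRKEY = {"1->2": "12", "2->1": "21"}
#: covariates computable from subject baseline data (safe to simulate from)
EXOGENOUS_COVARIATES = set(COVARIATE_FIELDS)
#: covariates derived from the observed event history (dropout model only)
DERIVED_COVARIATES = ("n_exacerbations", "state2_time")

RHAT_THRESHOLD = 1.05


@dataclass
class PriorConfig:
    """Vague priors: N(0, normal_var) on unconstrained globals, and
    tau ~ gamma(tau_shape, tau_rate) on the frailty precision."""

    normal_var: float = 1000.0
    tau_shape: float = 0.001
    tau_rate: float = 0.001


@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0


@dataclass
class ModelFormula:
    """What to fit: families, covariates and frailty per direction, plus an
    optional dropout submodel (attached via :func:`copdsm.dropout.attach_dropout`).

    Both directions share one family by default; ``family_21`` overrides the
    2->1 direction. ``shape_frailty`` additionally multiplies the shape by
    exp(eta) (off by default: the random effect is supported on the scale
    only).
    """

    family: Family = Family.LOGLOGISTIC
    family_21: Family | None = None
    covariates_12: tuple[str, ...] = ()
    covariates_21: tuple[str, ...] = ()
    frailty_12: bool = True
    frailty_21: bool = True
    shape_frailty: bool = False
    include_study_length: bool = True
    dropout: object | None = None  # DropoutFormula, see copdsm.dropout

    def __post_init__(self):
        self.family = Family(self.family)
        if self.family_21 is not None:
            self.family_21 = Family(self.family_21)
        for covs in (self.covariates_12, self.covariates_21):
            bad = set(covs) - EXOGENOUS_COVARIATES
            if bad:
                raise ValueError(f"unknown transition covariates: {sorted(bad)}")

    def family_for(self, direction: str) -> Family:
        if direction in ("2->1", "21") and self.family_21 is not None:
            return self.family_21
        return self.family

    def frailty_for(self, direction: str) -> bool:
        return self.frailty_12 if direction in ("1->2", "12") else self.frailty_21

    def covariates_for(self, direction: str) -> tuple[str, ...]:
        return self.covariates_12 if direction in ("1->2", "12") else self.covariates_21


# ---------------------------------------------------------------------------
# likelihood kernels
# ---------------------------------------------------------------------------


def sojourn_loglik(record, theta_kj: float, alpha_kj, family: Family) -> float:
    """Log-likelihood contribution of one sojourn: log h + log S if the
    transition was observed, log S alone if right-censored."""
    t = record.duration
    if t <= 0:
        raise ValueError(f"duration must be > 0 for {record}")
    ll = float(log_survival(family, t, theta_kj, alpha_kj))
    if record.event:
        ll += float(log_hazard(family, t, theta_kj, alpha_kj))
    if not math.isfinite(ll):
        raise FloatingPointError(f"non-finite log-likelihood for {record}")
    return ll


class _Component:
    """Arrays and likelihood evaluation for one model component (a transition
    direction, or the dropout time-to-event block)."""

    def __init__(self, name, family, t, event, X, coef_names, subj, n_subjects,
                 frailty, shape_frailty, logT_center):
        self.name = name
        self.family = Family(family)
        self.t = np.asarray(t, dtype=float)
        self.event = np.asarray(event, dtype=bool)
        self.X = np.asarray(X, dtype=float)
        self.coef_names = list(coef_names)
        self.subj = np.asarray(subj, dtype=np.intp)
        self.n_subjects = int(n_subjects)
        self.frailty = bool(frailty)
        self.shape_frailty = bool(shape_frailty) and self.family.has_shape
        self.logT_center = float(logT_center)
        self.dim = 1 + int(self.family.has_shape) + self.X.shape[1]
        # columns that are identically zero (e.g. centered log T in a fixed-
        # length design) leave the likelihood untouched; their coefficients
        # are sampled directly from the prior instead of by random walk
        k = self.dim - self.X.shape[1]
        self.prior_only = np.array(
            [
                k + j
                for j in range(self.X.shape[1])
                if self.X.shape[0] == 0 or np.max(np.abs(self.X[:, j])) < 1e-12
            ],
            dtype=np.intp,
        )

    # vector layout: [log_theta0, shape_u?, beta...]
    def split(self, v):
        k = 1
        shape_u = None
        if self.family.has_shape:
            shape_u = v[1]
            k = 2
        return v[0], shape_u, v[k:]

    def natural_alpha(self, shape_u):
        if shape_u is None:
            return None
        if self.family is Family.GOMPERTZ:
            return shape_u
        return np.exp(shape_u)

    def record_loglik(self, v, eta=None):
        """Per-record log-likelihood contributions; entries may be nan/-inf
        for out-of-domain proposals (callers treat those as rejections)."""
        log_theta0, shape_u, beta = self.split(v)
        lp = log_theta0 + self.X @ beta
        if self.frailty and eta is not None:
            lp = lp + eta[self.subj]
        alpha = self.natural_alpha(shape_u)
        if alpha is not None and self.family is not Family.GOMPERTZ:
            if not np.isfinite(alpha) or alpha <= 0:
                return np.full_like(self.t, -np.inf)
            if self.shape_frailty and eta is not None:
                alpha = alpha * np.exp(eta[self.subj])
        with np.errstate(over="ignore", under="ignore", invalid="ignore", divide="ignore"):
            theta = np.exp(lp)
            if not np.all(np.isfinite(theta)):
                return np.full_like(self.t, -np.inf)
            ll = _log_survival_raw(self.family, self.t, theta, alpha)
            if self.event.any():
                ev = self.event
                a_ev = alpha[ev] if isinstance(alpha, np.ndarray) and alpha.ndim else alpha
                ll[ev] += _log_hazard_raw(self.family, self.t[ev], theta[ev], a_ev)
        return ll

    def total_loglik(self, v, eta=None) -> float:
        ll = self.record_loglik(v, eta)
        s = ll.sum()
        return float(s) if np.isfinite(s) else -np.inf


def _log_survival_raw(family, t, theta, alpha):
    """log S without argument validation (sampler hot path)."""
    if family is Family.EXPONENTIAL:
        return -theta * t
    if family is Family.WEIBULL:
        return -theta * np.power(t, alpha)
    if family is Family.GOMPERTZ:
        small = np.abs(alpha) < 1e-12
        return np.where(small, -theta * t,
                        -(theta / np.where(small, 1.0, alpha)) * np.expm1(alpha * t))
    z = alpha * (np.log(t) - np.log(theta))
    return -np.logaddexp(0.0, z)


def _log_hazard_raw(family, t, theta, alpha):
    if family is Family.EXPONENTIAL:
        return np.log(theta) * np.ones_like(t)
    if family is Family.WEIBULL:
        return np.log(theta) + np.log(alpha) + (alpha - 1.0) * np.log(t)
    if family is Family.GOMPERTZ:
        return np.log(theta) + alpha * t
    z = alpha * (np.log(t) - np.log(theta))
    return np.log(alpha) + z - np.log(t) - np.logaddexp(0.0, z)


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


def _subject_index(dataset: TrialDataset) -> dict:
    return {sid: i for i, sid in enumerate(dataset.subject_ids)}

def _build_direction(dataset: TrialDataset, direction: str, formula: ModelFormula) -> _Component:
    state = 1 if direction == "1->2" else 2
    s = dataset.sojourns[dataset.sojourns["state"] == state]
    idx = _subject_index(dataset)
    subj = np.array([idx[x] for x in s["subject_id"]], dtype=np.intp)
    logT = np.log(dataset.subjects["study_length"].to_numpy(dtype=float))
    center = float(np.mean(logT))
    cols, names = [], []
    if formula.include_study_length:
        cols.append((logT - center)[subj])
        names.append("log_study_length")
    for c in formula.covariates_for(direction):
        if c not in dataset.subjects.columns:
            raise ValueError(f"covariate {c!r} absent from dataset")
        cols.append(dataset.subjects[c].to_numpy(dtype=float)[subj])
        names.append(c)
    X = np.column_stack(cols) if cols else np.zeros((len(s), 0))
    return _Component(
        name=_DIRKEY[direction],
        family=formula.family_for(direction),
        t=s["duration"].to_numpy(dtype=float),
        event=s["event"].to_numpy(dtype=bool),
        X=X,
        coef_names=names,
        subj=subj,
        n_subjects=dataset.n_subjects,
        frailty=formula.frailty_for(direction),
        shape_frailty=formula.shape_frailty,
        logT_center=center,
    )


def dropout_covariate_table(dataset: TrialDataset) -> pd.DataFrame:
    """Subject-level covariates available to the dropout model, including the
    event-derived ones (number of exacerbations, total days in state 2)."""
    tab = dataset.subjects.copy()
    tab["n_exacerbations"] = dataset.n_exacerbations()
    tab["state2_time"] = dataset.state_time(2)
    return tab


def _build_dropout(dataset: TrialDataset, formula) -> _Component:
    tab = dropout_covariate_table(dataset)
    t = dataset.follow_up_ends().to_numpy(dtype=float)
    event = dataset.subjects["dropout_flag"].to_numpy(dtype=bool)
    logT = np.log(dataset.subjects["study_length"].to_numpy(dtype=float))
    center = float(np.mean(logT))
    cols, names = [], []
    if formula.include_study_length:
        cols.append(logT - center)
        names.append("log_study_length")
    for c in formula.covariates:
        if c not in tab.columns:
            raise ValueError(f"dropout covariate {c!r} absent from dataset")
        cols.append(tab[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols) if cols else np.zeros((len(t), 0))
    return _Component(
        name="dropout",
        family=formula.family,
        t=t,
        event=event,
        X=X,
        coef_names=names,
        subj=np.arange(dataset.n_subjects, dtype=np.intp),
        n_subjects=dataset.n_subjects,
        frailty=False,
        shape_frailty=False,
        logT_center=center,
    )


def _init_vector(comp: _Component, rng) -> np.ndarray:
    events = int(comp.event.sum())
    rate = max(events, 1) / max(comp.t.sum(), 1.0)
    v = np.zeros(comp.dim)
    if comp.family is Family.LOGLOGISTIC:
        med = float(np.median(comp.t[comp.event])) if events else 1.0 / rate
        v[0] = math.log(max(med, 1e-3))
    else:
        v[0] = math.log(rate)
    scales = np.full(comp.dim, 0.1)
    if comp.family is Family.GOMPERTZ:
        scales[1] = 1e-3  # raw shape; |alpha| ~ 1e-3/day in practice
    v += scales * rng.standard_normal(comp.dim)
    return v


class _AdaptiveRW:
    """Random-walk Metropolis proposal with Haario-style covariance
    adaptation during warmup and Robbins-Monro scale tuning."""

    def __init__(self, dim, init_sd, target=None):
        self.dim = dim
        self.target = target if target is not None else (0.44 if dim == 1 else 0.3)
        self.log_scale = 0.0
        self.chol = np.diag(np.asarray(init_sd, dtype=float))
        self.count = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim))

    def propose(self, rng) -> np.ndarray:
        return math.exp(self.log_scale) * (self.chol @ rng.standard_normal(self.dim))

    def adapt(self, acc_prob, x, it):
        self.log_scale += (it + 1) ** -0.6 * (acc_prob - self.target)
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += np.outer(delta, x - self.mean)
        if self.count >= max(4 * self.dim, 20) and self.count % 25 == 0:
            cov = self.m2 / (self.count - 1)
            cov = (2.38**2 / self.dim) * cov + 1e-9 * np.eye(self.dim)
            try:
                self.chol = np.linalg.cholesky(cov)
                self.log_scale = 0.0
            except np.linalg.LinAlgError:
                pass


def _run_chain(components, prior: PriorConfig, warmup, draws, rng):
    keys = list(components)
    n_subj = next(iter(components.values())).n_subjects
    frailty_keys = [k for k in keys if components[k].frailty]

    v = {k: _init_vector(components[k], rng) for k in keys}
    eta = {k: np.zeros(n_subj) for k in keys}
    tau = {k: 10.0 for k in frailty_keys}

    rec_ll = {k: components[k].record_loglik(v[k], eta[k]) for k in keys}
    tot = {}
    for k in keys:
        s = rec_ll[k].sum()
        tot[k] = float(s) if np.isfinite(s) else -np.inf

    samplers = {}
    for k in keys:
        comp = components[k]
        init_sd = np.full(comp.dim, 0.05)
        if comp.family is Family.GOMPERTZ:
            init_sd[1] = 1e-4
        samplers[k] = _AdaptiveRW(comp.dim, init_sd)
    # per-subject step sizes: subjects with many sojourns need much smaller
    # frailty steps than event-free ones
    eta_step = {k: np.full(n_subj, 0.3) for k in frailty_keys}

    inv2var = 0.5 / prior.normal_var
    out_v = {k: np.empty((draws, components[k].dim)) for k in keys}
    out_eta = {k: np.empty((draws, n_subj)) for k in frailty_keys}
    out_tau = {k: np.empty(draws) for k in frailty_keys}
    out_dev = np.empty(draws)

    prior_sd = math.sqrt(prior.normal_var)
    offset_step = {k: 0.3 for k in frailty_keys}
    ncp_step = {k: 0.3 for k in frailty_keys}
    for it in range(warmup + draws):
        adapting = it < warmup
        for k in keys:
            comp = components[k]
            if len(comp.prior_only):
                v[k][comp.prior_only] = prior_sd * rng.standard_normal(len(comp.prior_only))
            prop = v[k] + samplers[k].propose(rng)
            if len(comp.prior_only):
                prop[comp.prior_only] = v[k][comp.prior_only]
            ll_vec = comp.record_loglik(prop, eta[k])
            s = ll_vec.sum()
            tot_prop = float(s) if np.isfinite(s) else -np.inf
            logr = (tot_prop - inv2var * prop @ prop) - (tot[k] - inv2var * v[k] @ v[k])
            acc_prob = math.exp(min(0.0, logr)) if np.isfinite(logr) else 0.0
            if math.log(rng.random()) < logr:
                v[k], rec_ll[k], tot[k] = prop, ll_vec, tot_prop
            if adapting:
                samplers[k].adapt(acc_prob, v[k].copy(), it)
        for k in frailty_keys:
            comp = components[k]
            for _sweep in range(2):
                prop_eta = eta[k] + eta_step[k] * rng.standard_normal(n_subj)
                ll_vec = comp.record_loglik(v[k], prop_eta)
                with np.errstate(invalid="ignore"):
                    per_new = np.bincount(comp.subj, weights=ll_vec, minlength=n_subj)
                    per_old = np.bincount(comp.subj, weights=rec_ll[k], minlength=n_subj)
                    logr = (per_new - per_old
                            - 0.5 * tau[k] * (prop_eta**2 - eta[k] ** 2))
                with np.errstate(invalid="ignore"):
                    acc_prob = np.exp(np.minimum(0.0, logr))
                acc_prob[~np.isfinite(acc_prob)] = 0.0
                accept = np.log(rng.random(n_subj)) < logr
                eta[k] = np.where(accept, prop_eta, eta[k])
                rec_ll[k] = np.where(accept[comp.subj], ll_vec, rec_ll[k])
                if adapting:
                    eta_step[k] *= np.exp((it + 1) ** -0.6 * (acc_prob - 0.44))
            s = rec_ll[k].sum()
            tot[k] = float(s) if np.isfinite(s) else -np.inf
            # translation move: eta -> eta + c, log_theta0 -> log_theta0 - c
            # leaves every linked scale (hence the likelihood) unchanged, so
            # only the priors enter; breaks the frailty-mean/intercept ridge
            if not comp.shape_frailty:
                c = offset_step[k] * rng.standard_normal()
                se = float(eta[k].sum())
                logr_c = (
                    -0.5 * tau[k] * (2 * c * se + n_subj * c * c)
                    - inv2var * ((v[k][0] - c) ** 2 - v[k][0] ** 2)
                )
                acc_c = math.exp(min(0.0, logr_c))
                if math.log(rng.random()) < logr_c:
                    eta[k] = eta[k] + c
                    v[k][0] -= c
                if adapting:
                    offset_step[k] *= math.exp((it + 1) ** -0.6 * (acc_c - 0.44))
            tau[k] = rng.gamma(
                prior.tau_shape + 0.5 * n_subj,
                1.0 / (prior.tau_rate + 0.5 * float(eta[k] @ eta[k])),
            )
            # interweaved non-centered update: holding q = eta/sigma fixed,
            # move w = log sigma by MH (prior on w from tau ~ gamma(a, b):
            # log p(w) = -2 a w - b exp(-2w) + const); rescales the whole
            # frailty vector at once, which the per-subject walk cannot do
            w = -0.5 * math.log(tau[k])
            w_prop = w + ncp_step[k] * rng.standard_normal()
            prop_eta = eta[k] * math.exp(w_prop - w)
            ll_vec = comp.record_loglik(v[k], prop_eta)
            s = ll_vec.sum()
            tot_prop = float(s) if np.isfinite(s) else -np.inf
            logr = (
                tot_prop - tot[k]
                - 2 * prior.tau_shape * (w_prop - w)
                - prior.tau_rate * (math.exp(-2 * w_prop) - math.exp(-2 * w))
            )
            acc_prob = math.exp(min(0.0, logr)) if np.isfinite(logr) else 0.0
            if math.log(rng.random()) < logr:
                eta[k] = prop_eta
                rec_ll[k] = ll_vec
                tot[k] = tot_prop
                tau[k] = math.exp(-2 * w_prop)
            if adapting:
                ncp_step[k] *= math.exp((it + 1) ** -0.6 * (acc_prob - 0.44))
        if not adapting:
            j = it - warmup
            for k in keys:
                out_v[k][j] = v[k]
            for k in frailty_keys:
                out_eta[k][j] = eta[k]
                out_tau[k][j] = tau[k]
            out_dev[j] = -2.0 * sum(tot.values())
    return out_v, out_eta, out_tau, out_dev


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorFit:
    """MCMC draws, deviance trace, DIC and convergence summaries."""

    draws: dict
    eta_draws: dict
    deviance: np.ndarray
    dic: float
    p_d: float
    rhat: dict
    ess: dict
    warnings: list
    formula: ModelFormula
    prior: PriorConfig
    sampler: SamplerConfig
    subject_ids: list
    centers: dict
    design_study_length: float
    component_names: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def median(self, name: str) -> float:
        return float(np.median(self.flat(name)))

    def ci(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        a = 100 * (1 - prob) / 2
        lo, hi = np.percentile(self.flat(name), [a, 100 - a])
        return float(lo), float(hi)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.draws:
            lo, hi = self.ci(name)
            rows.append(
                {
                    "parameter": name,
                    "median": self.median(name),
                    "q2.5": lo,
                    "q97.5": hi,
                    "rhat": self.rhat.get(name, np.nan),
                    "ess": self.ess.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def draws_frame(self) -> pd.DataFrame:
        """Tidy draws table: chain, iter, parameter, value."""
        frames = []
        for name, arr in self.draws.items():
            c, d = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d),
                        "iter": np.tile(np.arange(d), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @property
    def converged(self) -> bool:
        return not any(w.startswith("convergence") for w in self.warnings)

    # -- reconstruction of natural-scale specs ---------------------------
    def n_total_draws(self) -> int:
        return self.n_chains * self.n_draws

    def _coef(self, key: str, name: str, i: int) -> float:
        full = f"beta_{key}_{name}"
        return float(self.flat(full)[i]) if full in self.draws else 0.0

    def transition_spec(
        self, direction: str, i: int, pin_study_length: float | None = None
    ) -> TransitionSpec:
        """Natural-scale :class:`TransitionSpec` at flattened draw ``i``.

        ``theta0`` in the draws is referenced to the geometric-mean study
        length; by default the returned spec folds the centering back so that
        applying the spec's link with raw log T reproduces the fitted scales
        exactly. ``pin_study_length`` instead freezes the study-length term
        at the given design length and removes it from the spec — required
        when simulating a design whose length differs from the fitted one,
        where extrapolating the (often weakly identified) log-T coefficient
        is meaningless."""
        key = _DIRKEY[direction]
        fam = self.formula.family_for(direction)
        theta0 = float(self.flat(f"theta0_{key}")[i])
        alpha = float(self.flat(f"alpha_{key}")[i]) if fam.has_shape else None
        beta = {}
        for name in self.component_names.get(key, []):
            beta[name] = self._coef(key, name, i)
        if "log_study_length" in beta:
            if pin_study_length is not None:
                theta0 *= math.exp(
                    beta.pop("log_study_length")
                    * (math.log(pin_study_length) - self.centers[key])
                )
            else:
                theta0 *= math.exp(-beta["log_study_length"] * self.centers[key])
        sigma2 = (
            float(self.flat(f"sigma2_{key}")[i])
            if f"sigma2_{key}" in self.draws
            else 0.0
        )
        return TransitionSpec(
            state_from=1 if direction == "1->2" else 2,
            family=fam,
            theta0=theta0,
            alpha=alpha,
            beta=beta,
            sigma2=sigma2,
        )

    def dropout_spec(self, i: int):
        """Natural-scale dropout spec at flattened draw ``i`` (None when no
        dropout submodel is attached, or when its covariates are derived from
        the event history and therefore cannot seed a forward simulation)."""
        if self.formula.dropout is None or "theta0_dropout" not in self.draws:
            return None
        names = self.component_names.get("dropout", [])
        if any(n in DERIVED_COVARIATES for n in names):
            return None
        from .dropout import DropoutSpec

        fam = self.formula.dropout.family
        theta0 = float(self.flat("theta0_dropout")[i])
        alpha = float(self.flat("alpha_dropout")[i]) if Family(fam).has_shape else None
        beta = {n: self._coef("dropout", n, i) for n in names}
        if "log_study_length" in beta:
            theta0 *= math.exp(-beta["log_study_length"] * self.centers["dropout"])
        return DropoutSpec(family=fam, theta0=theta0, alpha=alpha, beta=beta)


def significant(fit: PosteriorFit, name: str, prob: float = 0.95) -> bool:
    """The effect-selection rule: 0 outside the credible interval."""
    lo, hi = fit.ci(name, prob)
    return lo > 0 or hi < 0


# ---------------------------------------------------------------------------
# public fitting entry points
# ---------------------------------------------------------------------------


def _natural_names(key: str, comp: _Component) -> list[str]:
    names = [f"theta0_{key}"]
    if comp.family.has_shape:
        names.append(f"alpha_{key}")
    names += [f"beta_{key}_{n}" for n in comp.coef_names]
    return names


def _to_natural(key: str, comp: _Component, arr: np.ndarray) -> dict:
    """Map unconstrained draw matrix (chains, draws, dim) to named arrays."""
    out = {f"theta0_{key}": np.exp(arr[..., 0])}
    k = 1
    if comp.family.has_shape:
        if comp.family is Family.GOMPERTZ:
            out[f"alpha_{key}"] = arr[..., 1].copy()
        else:
            out[f"alpha_{key}"] = np.exp(arr[..., 1])
        k = 2
    for j, n in enumerate(comp.coef_names):
        out[f"beta_{key}_{n}"] = arr[..., k + j].copy()
    return out


def _convergence(draws: dict) -> tuple[dict, dict, list]:
    import arviz as az

    idata = az.from_dict(posterior={k: v for k, v in draws.items()})
    rh = az.rhat(idata)
    es = az.ess(idata)
    rhat = {k: float(rh[k].values) for k in draws}
    ess = {k: float(es[k].values) for k in draws}
    warnings = []
    bad = {k: r for k, r in rhat.items() if np.isfinite(r) and r > RHAT_THRESHOLD}
    if bad:
        worst = max(bad.values())
        warnings.append(
            f"convergence: split-Rhat > {RHAT_THRESHOLD} for "
            f"{sorted(bad)} (worst {worst:.3f})"
        )
    return rhat, ess, warnings


def fit(
    dataset: TrialDataset,
    formula: ModelFormula | None = None,
    prior: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
) -> PosteriorFit:
    """Run MCMC for the two-state model (with the dropout submodel when the
    formula attaches one) and return a :class:`PosteriorFit`."""
    if dataset.n_subjects == 0 or len(dataset.sojourns) == 0:
        raise ValueError("dataset must contain at least one sojourn")
    formula = formula or ModelFormula()
    prior = prior or PriorConfig()
    sampler = sampler or SamplerConfig()

    components = {
        "12": _build_direction(dataset, "1->2", formula),
        "21": _build_direction(dataset, "2->1", formula),
    }
    warnings: list[str] = []
    if formula.dropout is not None:
        comp = _build_dropout(dataset, formula.dropout)
        if comp.event.sum() == 0:
            warnings.append(
                "dropout: no dropout events observed; covariate effects are "
                "unidentifiable (prior-driven)"
            )
        components["dropout"] = comp

    seeds = np.random.SeedSequence(sampler.seed).spawn(sampler.chains)
    chain_v = {k: [] for k in components}
    chain_eta = {k: [] for k in components if components[k].frailty}
    chain_tau = {k: [] for k in components if components[k].frailty}
    chain_dev = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        out_v, out_eta, out_tau, out_dev = _run_chain(
            components, prior, sampler.warmup, sampler.draws, rng
        )
        for k in components:
            chain_v[k].append(out_v[k])
        for k in chain_eta:
            chain_eta[k].append(out_eta[k])
            chain_tau[k].append(out_tau[k])
        chain_dev.append(out_dev)

    draws: dict[str, np.ndarray] = {}
    component_names: dict[str, list] = {}
    centers: dict[str, float] = {}
    v_stacked = {}
    for k, comp in components.items():
        arr = np.stack(chain_v[k])  # (chains, draws, dim)
        v_stacked[k] = arr
        draws.update(_to_natural(k, comp, arr))
        component_names[k] = comp.coef_names
        centers[k] = comp.logT_center
    eta_draws = {}
    for k in chain_eta:
        eta_draws[k] = np.stack(chain_eta[k])
        draws[f"sigma2_{k}"] = 1.0 / np.stack(chain_tau[k])
    deviance = np.stack(chain_dev)

    # DIC: plug in posterior means of the unconstrained globals and frailties
    dbar = float(deviance.mean())
    dev_hat = 0.0
    for k, comp in components.items():
        v_mean = v_stacked[k].reshape(-1, comp.dim).mean(axis=0)
        eta_mean = (
            eta_draws[k].reshape(-1, comp.n_subjects).mean(axis=0)
            if k in eta_draws
            else np.zeros(comp.n_subjects)
        )
        dev_hat += -2.0 * comp.total_loglik(v_mean, eta_mean)
    p_d = dbar - dev_hat
    dic_value = dbar + p_d

    rhat, ess, conv_warnings = _convergence(draws)
    warnings.extend(conv_warnings)

    return PosteriorFit(
        draws=draws,
        eta_draws=eta_draws,
        deviance=deviance,
        dic=dic_value,
        p_d=p_d,
        rhat=rhat,
        ess=ess,
        warnings=warnings,
        formula=formula,
        prior=prior,
        sampler=sampler,
        subject_ids=dataset.subject_ids,
        centers=centers,
        design_study_length=float(dataset.subjects["study_length"].median()),
        component_names=component_names,
    )


def dic(fit_result: PosteriorFit) -> tuple[float, float]:
    """(DIC, pD) with DIC = Dbar + pD and pD = Dbar - D(posterior means)."""
    return fit_result.dic, fit_result.p_d


# ---------------------------------------------------------------------------
# fixed-parameter likelihood (oracle-friendly, natural parameterisation)
# ---------------------------------------------------------------------------


def total_loglik(dataset: TrialDataset, formula: ModelFormula, params: dict) -> float:
    """Joint log-likelihood at fixed natural-scale parameters.

    ``params`` maps ``"12"`` / ``"21"`` (and ``"dropout"`` when attached) to
    dicts with keys ``theta0``, ``alpha``, ``beta`` (name -> coefficient,
    including ``"log_study_length"``), ``sigma2`` and ``eta`` (subject_id ->
    frailty, defaulting to 0). Includes the frailty log-prior terms
    N(eta; 0, sigma2) for directions with active frailty and the dropout
    submodel terms when attached. Domain violations return ``-inf``.
    """
    total = 0.0
    try:
        for direction in DIRECTIONS:
            key = _DIRKEY[direction]
            p = params[key]
            fam = formula.family_for(direction)
            beta = dict(p.get("beta", {}))
            eta_map = p.get("eta", {})
            state = 1 if direction == "1->2" else 2
            s = dataset.sojourns[dataset.sojourns["state"] == state]
            logT = np.log(dataset.subjects["study_length"])
            for row in s.itertuples(index=False):
                sid = str(row.subject_id)
                lp = math.log(p["theta0"]) + float(eta_map.get(sid, 0.0))
                for name, coef in beta.items():
                    if name == "log_study_length":
                        lp += coef * float(logT.loc[sid])
                    else:
                        lp += coef * float(dataset.subjects.loc[sid, name])
                theta = math.exp(lp)
                ll = float(log_survival(fam, row.duration, theta, p.get("alpha")))
                if row.event:
                    ll += float(log_hazard(fam, row.duration, theta, p.get("alpha")))
                total += ll
            sigma2 = p.get("sigma2")
            if formula.frailty_for(direction) and sigma2 is not None and sigma2 > 0:
                for sid in dataset.subject_ids:
                    e = float(eta_map.get(sid, 0.0))
                    total += -0.5 * math.log(2 * math.pi * sigma2) - e * e / (2 * sigma2)
        if formula.dropout is not None and "dropout" in params:
            p = params["dropout"]
            comp = _build_dropout(dataset, formula.dropout)
            tab = dropout_covariate_table(dataset)
            fam = Family(formula.dropout.family)
            for i, sid in enumerate(dataset.subject_ids):
                lp = math.log(p["theta0"])
                for name, coef in p.get("beta", {}).items():
                    if name == "log_study_length":
                        lp += coef * math.log(float(tab.loc[sid, "study_length"]))
                    else:
                        lp += coef * float(tab.loc[sid, name])
                theta = math.exp(lp)
                ll = float(log_survival(fam, comp.t[i], theta, p.get("alpha")))
                if comp.event[i]:
                    ll += float(log_hazard(fam, comp.t[i], theta, p.get("alpha")))
                total += ll
    except (ValueError, OverflowError):
        return -np.inf
    if not np.isfinite(total):
        return -np.inf
    return float(total)
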