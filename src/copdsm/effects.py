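"""Drug-effect summaries and trial-design exploration.

Drug effect is summarised per transition direction by the posterior of the
transition-rate ratio ``h_ref(t) / h_alt(t)`` (typically placebo/active — a
ratio above 1 on the 1->2 direction means the active arm delays exacerbation
onset) and by the transition probability ``F(t) = 1 - S(t)`` under a chosen
covariate stratum. Curves are population-level: the frailty is held at its
median (0 on the log scale) and the study-length term at the design length,
so it cancels in ratios.

Design exploration refits the model after subsampling subjects per arm
without replacement or truncating follow-up to a shorter study, and the
extrapolation check fits on truncated data and projects exacerbation counts
to longer horizons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialDataset
from .families import log_hazard, log_survival
from .inference import (
    _DIRKEY,
    ModelFormula,
    PosteriorFit,
    SamplerConfig,
    fit as fit_model,
)

__all__ = [
    "RateRatioCurve",
    "TransitionProbCurve",
    "rate_ratio",
    "transition_probability",
    "truncate_followup",
    "subsample",
    "design_experiment",
    "extrapolate",
    "DesignResult",
    "ExtrapolationResult",
]


def _linked_theta_draws(fit: PosteriorFit, direction: str, covariates: dict,
                        study_length: float) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-draw (theta, alpha) under given covariate values, frailty at 0."""
    key = _DIRKEY[direction]
    unknown = set(covariates) - set(fit.component_names.get(key, []))
    if unknown:
        raise ValueError(
            f"covariates {sorted(unknown)} not in the fitted {direction} formula"
        )
    lp = np.log(fit.flat(f"theta0_{key}"))
    for name in fit.component_names.get(key, []):
        coef = fit.flat(f"beta_{key}_{name}")
        if name == "log_study_length":
            x = math.log(study_length) - fit.centers[key]
        else:
            x = float(covariates.get(name, 0.0))
        lp = lp + coef * x
    theta = np.exp(lp)
    fam = fit.formula.family_for(direction)
    alpha = fit.flat(f"alpha_{key}") if fam.has_shape else None
    return theta, alpha


def _grid(fit: PosteriorFit, time_grid, study_length) -> np.ndarray:
    if time_grid is not None:
        return np.asarray(time_grid, dtype=float)
    T = study_length or fit.design_study_length
    return np.arange(1.0, T + 1.0)  # 1-day steps over (0, T]


@dataclass
class RateRatioCurve:
    direction: str
    time: np.ndarray
    median: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    @property
    def significant(self) -> bool:
        """True when the 95% band excludes 1 anywhere on the grid."""
        return bool(np.any((self.lo > 1.0) | (self.hi < 1.0)))

    def df(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "median": self.median,
                             "lo": self.lo, "hi": self.hi})


@dataclass
class TransitionProbCurve:
    direction: str
    stratum: str
    time: np.ndarray
    median: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def df(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "median": self.median,
                             "lo": self.lo, "hi": self.hi})


def rate_ratio(
    fit: PosteriorFit,
    direction: str = "1->2",
    reference: dict | None = None,
    alternative: dict | None = None,
    time_grid=None,
    study_length: float | None = None,
) -> RateRatioCurve:
    """Posterior transition-rate ratio h_ref(t)/h_alt(t) over a time grid.

    Default contrast is placebo (treatment=0) over active (treatment=1)."""
    reference = {"treatment": 0} if reference is None else reference
    alternative = {"treatment": 1} if alternative is None else alternative
    T = study_length or fit.design_study_length
    t = _grid(fit, time_grid, T)
    fam = fit.formula.family_for(direction)
    th_ref, alpha = _linked_theta_draws(fit, direction, reference, T)
    th_alt, _ = _linked_theta_draws(fit, direction, alternative, T)
    a = alpha[:, None] if alpha is not None else None
    log_ratio = (
        log_hazard(fam, t[None, :], th_ref[:, None], a)
        - log_hazard(fam, t[None, :], th_alt[:, None], a)
    )
    ratio = np.exp(log_ratio)
    lo, med, hi = np.percentile(ratio, [2.5, 50, 97.5], axis=0)
    return RateRatioCurve(direction=direction, time=t, median=med, lo=lo, hi=hi)


def transition_probability(
    fit: PosteriorFit,
    direction: str = "1->2",
    stratum: dict | None = None,
    time_grid=None,
    study_length: float | None = None,
    label: str | None = None,
) -> TransitionProbCurve:
    """Posterior transition probability F(t) = 1 - S(t) under a covariate
    stratum, with pointwise credible bands."""
    stratum = stratum or {}
    T = study_length or fit.design_study_length
    t = _grid(fit, time_grid, T)
    fam = fit.formula.family_for(direction)
    theta, alpha = _linked_theta_draws(fit, direction, stratum, T)
    a = alpha[:, None] if alpha is not None else None
    F = -np.expm1(log_survival(fam, t[None, :], theta[:, None], a))
    lo, med, hi = np.percentile(F, [2.5, 50, 97.5], axis=0)
    name = label or ", ".join(f"{k}={v}" for k, v in stratum.items()) or "reference"
    return TransitionProbCurve(direction=direction, stratum=name, time=t,
                               median=med, lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# design modifications
# ---------------------------------------------------------------------------


def truncate_followup(dataset: TrialDataset, L: float) -> TrialDataset:
    """Administratively truncate the trial at day L: sojourns crossing L are
    re-censored at L, later sojourns dropped, study lengths and the dropout
    flags recomputed. L equal to the study length leaves data unchanged."""
    if L <= 0:
        raise ValueError("truncation length must be > 0")
    if L > float(dataset.subjects["study_length"].max()):
        raise ValueError("truncation length exceeds every study length")
    subj = dataset.subjects.copy()
    fu_old = dataset.follow_up_ends()
    fu_new = np.minimum(fu_old.to_numpy(dtype=float), L)
    T_new = np.minimum(subj["study_length"].to_numpy(dtype=float), L)
    subj["study_length"] = T_new
    subj["dropout_time"] = np.where(fu_new < T_new, fu_new, np.nan)
    subj["dropout_flag"] = fu_new < T_new - dataset.dropout_window
    fu_map = dict(zip(dataset.subjects.index, fu_new))
    rows = []
    for sid, grp in dataset.sojourns.groupby("subject_id", sort=False):
        end = fu_map[sid]
        t = 0.0
        for r in grp.sort_values("episode").itertuples(index=False):
            if t >= end:
                break
            if t + r.duration <= end:
                rows.append((sid, r.episode, r.state, r.duration, bool(r.event)))
                t += r.duration
            else:
                rows.append((sid, r.episode, r.state, end - t, False))
                break
    sojourns = pd.DataFrame(rows, columns=["subject_id", "episode", "state",
                                           "duration", "event"])
    return TrialDataset(subj, sojourns, dropout_window=dataset.dropout_window)


def subsample(dataset: TrialDataset, n_per_arm: int, rng) -> TrialDataset:
    """Sample n subjects per treatment arm without replacement."""
    keep = []
    for arm, grp in dataset.subjects.groupby("treatment", sort=True):
        if n_per_arm > len(grp):
            raise ValueError(
                f"requested {n_per_arm} subjects but arm {arm} has {len(grp)}"
            )
        keep.extend(rng.choice(grp.index.to_numpy(), size=n_per_arm, replace=False))
    keep = set(keep)
    subj = dataset.subjects.loc[dataset.subjects.index.isin(keep)]
    soj = dataset.sojourns[dataset.sojourns["subject_id"].isin(keep)]
    return TrialDataset(subj, soj.reset_index(drop=True),
                        dropout_window=dataset.dropout_window)


@dataclass
class DesignResult:
    curve: RateRatioCurve
    significant: bool
    fit: PosteriorFit
    dataset: TrialDataset


def design_experiment(
    dataset: TrialDataset,
    formula: ModelFormula,
    subsample_per_arm: int | None = None,
    truncate_days: float | None = None,
    sampler: SamplerConfig | None = None,
    direction: str = "1->2",
    seed: int = 0,
) -> DesignResult:
    """Apply a design modification (fewer subjects per arm and/or shorter
    follow-up), refit, and report the placebo/active rate-ratio curve with
    its significance verdict (95% band excludes 1 somewhere)."""
    mod = dataset
    if truncate_days is not None:
        mod = truncate_followup(mod, truncate_days)
    if subsample_per_arm is not None:
        mod = subsample(mod, subsample_per_arm, np.random.default_rng(seed))
    fit_res = fit_model(mod, formula, sampler=sampler)
    curve = rate_ratio(fit_res, direction=direction)
    return DesignResult(curve=curve, significant=curve.significant,
                        fit=fit_res, dataset=mod)


@dataclass
class ExtrapolationResult:
    horizon: float
    table: pd.DataFrame  # exacerbation-count VPC at the horizon
    mean_interval_width: float

    @property
    def coverage(self) -> float:
        t = self.table
        return float(((t["observed"] >= t["lo"]) & (t["observed"] <= t["hi"])).mean())


def extrapolate(
    fit_res: PosteriorFit,
    horizon_days: float,
    observed: TrialDataset,
    n_replicates: int = 100,
    seed: int = 0,
) -> ExtrapolationResult:
    """Project a fit (typically on truncated data) to a longer horizon and
    compare the predicted exacerbation-count distribution with data observed
    over that horizon. Interval widths grow with the horizon."""
    from .simulate import simulate_matched

    obs_at_h = observed
    if horizon_days < float(observed.subjects["study_length"].max()) - 1e-9:
        obs_at_h = truncate_followup(observed, horizon_days)
    design = obs_at_h.subjects.copy()
    design["study_length"] = np.minimum(
        design["study_length"].to_numpy(dtype=float), horizon_days
    )
    design_ds = TrialDataset(
        design.assign(dropout_time=np.nan, dropout_flag=False),
        obs_at_h.sojourns,
        dropout_window=obs_at_h.dropout_window,
    )
    n_total = fit_res.n_total_draws()
    obs_counts = obs_at_h.n_exacerbations().to_numpy()
    rep_counts = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        i = int(rng.integers(n_total))
        pin = fit_res.design_study_length
        rep = simulate_matched(
            design_ds,
            fit_res.transition_spec("1->2", i, pin_study_length=pin),
            fit_res.transition_spec("2->1", i, pin_study_length=pin),
            fit_res.dropout_spec(i),
            rng,
        )
        rep_counts.append(rep.n_exacerbations().to_numpy())
    k_top = int(max(obs_counts.max(initial=0), max(c.max() for c in rep_counts)))
    rows = []
    widths = []
    for k in range(k_top + 1):
        rep_k = np.array([(c == k).sum() for c in rep_counts])
        lo, med, hi = np.percentile(rep_k, [2.5, 50, 97.5])
        widths.append(hi - lo)
        rows.append({"count": k, "observed": int((obs_counts == k).sum()),
                     "lo": lo, "median": med, "hi": hi})
    return ExtrapolationResult(
        horizon=horizon_days,
        table=pd.DataFrame(rows),
        mean_interval_width=float(np.mean(widths)),
    )
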