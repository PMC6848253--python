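"""Parametric time-to-dropout model, fitted separately and attachable to the
two-state model.

Dropout is treated as a missing-at-random time-to-event process: a subject is
a dropout when their last observation precedes the nominal study end by more
than the dropout window (30 days by default, 14 for short studies). Candidate
families are exponential, Weibull and log-logistic; covariates may include
baseline quantities and — for the separate conditional analysis — quantities
derived from the observed event history (number of exacerbations, total time
in state 2). Under MAR the joint likelihood of the integrated model
factorises, so attaching the dropout block leaves the transition-parameter
posterior unchanged up to Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .families import COVARIATE_FIELDS, Family
from .data import TrialDataset
from .inference import (
    DERIVED_COVARIATES,
    ModelFormula,
    PosteriorFit,
    PriorConfig,
    SamplerConfig,
)

__all__ = ["DropoutSpec", "DropoutFormula", "fit_dropout", "attach_dropout"]

_DROPOUT_FAMILIES = (Family.EXPONENTIAL, Family.WEIBULL, Family.LOGLOGISTIC)


@dataclass
class DropoutSpec:
    """Simulation truth for the dropout process: family, scale, shape and
    covariate coefficients (same log-linear link as the transitions).
    Only baseline covariates may appear — simulating dropout from
    event-derived covariates would break the MAR assumption."""

    family: Family = Family.LOGLOGISTIC
    theta0: float = 2000.0
    alpha: float | None = 1.5
    beta: dict = field(default_factory=dict)
    dropout_window_days: float = 30.0

    def __post_init__(self):
        self.family = Family(self.family)
        if self.family not in _DROPOUT_FAMILIES:
            raise ValueError("dropout family must be exponential, weibull or loglogistic")
        if self.theta0 <= 0:
            raise ValueError("theta0 must be > 0")
        if self.family.has_shape and (self.alpha is None or self.alpha <= 0):
            raise ValueError(f"{self.family.value} dropout requires alpha > 0")
        bad = set(self.beta) - set(COVARIATE_FIELDS) - {"log_study_length"}
        if bad:
            raise ValueError(f"dropout simulation covariates must be baseline: {sorted(bad)}")


@dataclass
class DropoutFormula:
    """What the dropout submodel estimates: family plus covariate names,
    which may include the event-derived ``n_exacerbations`` and
    ``state2_time`` (treated as fixed observed covariates)."""

    family: Family = Family.LOGLOGISTIC
    covariates: tuple[str, ...] = ("disease_stage",)
    include_study_length: bool = False

    def __post_init__(self):
        self.family = Family(self.family)
        if self.family not in _DROPOUT_FAMILIES:
            raise ValueError("dropout family must be exponential, weibull or loglogistic")
        allowed = set(COVARIATE_FIELDS) | set(DERIVED_COVARIATES)
        bad = set(self.covariates) - allowed
        if bad:
            raise ValueError(f"unknown dropout covariates: {sorted(bad)}")


def fit_dropout(
    dataset: TrialDataset,
    formula: DropoutFormula | None = None,
    prior: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
) -> PosteriorFit:
    """Fit the dropout model alone (the separate analysis): the two-state
    transition likelihood is not touched; only the subject-level
    time-to-dropout records enter."""
    from . import inference

    formula = formula or DropoutFormula()
    comp = inference._build_dropout(dataset, formula)
    prior = prior or PriorConfig()
    sampler = sampler or SamplerConfig()
    warnings = []
    if comp.event.sum() == 0:
        warnings.append(
            "dropout: no dropout events observed; covariate effects are "
            "unidentifiable (prior-driven)"
        )

    import numpy as np

    seeds = np.random.SeedSequence(sampler.seed).spawn(sampler.chains)
    chain_v, chain_dev = [], []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        out_v, _, _, out_dev = inference._run_chain(
            {"dropout": comp}, prior, sampler.warmup, sampler.draws, rng
        )
        chain_v.append(out_v["dropout"])
        chain_dev.append(out_dev)
    arr = np.stack(chain_v)
    draws = inference._to_natural("dropout", comp, arr)
    deviance = np.stack(chain_dev)
    dbar = float(deviance.mean())
    v_mean = arr.reshape(-1, comp.dim).mean(axis=0)
    dev_hat = -2.0 * comp.total_loglik(v_mean)
    p_d = dbar - dev_hat
    rhat, ess, conv = inference._convergence(draws)
    warnings.extend(conv)

    shell = ModelFormula(family=formula.family, frailty_12=False, frailty_21=False,
                         include_study_length=formula.include_study_length,
                         dropout=formula)
    return PosteriorFit(
        draws=draws,
        eta_draws={},
        deviance=deviance,
        dic=dbar + p_d,
        p_d=p_d,
        rhat=rhat,
        ess=ess,
        warnings=warnings,
        formula=shell,
        prior=prior,
        sampler=sampler,
        subject_ids=dataset.subject_ids,
        centers={"dropout": comp.logT_center},
        design_study_length=float(dataset.subjects["study_length"].median()),
        component_names={"dropout": comp.coef_names},
    )


def attach_dropout(formula: ModelFormula, dropout: DropoutFormula) -> ModelFormula:
    """Integrate the dropout submodel into a two-state formula: the joint
    likelihood is the sum of the two components (independence under MAR) and
    a joint fit exposes both parameter blocks."""
    if not isinstance(dropout, DropoutFormula):
        raise TypeError("dropout must be a DropoutFormula")
    return replace(formula, dropout=dropout)
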