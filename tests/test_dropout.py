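"""Dropout submodel: window rule, censored-only likelihood, MAR
factorisation of the integrated model, and family selection by DIC."""

import math

import numpy as np
import pytest

from copdsm import (
    DropoutFormula,
    DropoutSpec,
    Family,
    ModelFormula,
    SamplerConfig,
    attach_dropout,
    fit,
    fit_dropout,
    reference_trial_config,
    simulate_trial,
    total_loglik,
)
from copdsm.families import log_survival
from copdsm.inference import _build_dropout

SPARSE_DROPOUT = DropoutSpec(
    family=Family.LOGLOGISTIC, theta0=3500.0, alpha=1.5,
    beta={"disease_stage": -0.68},
)


def dropout_dataset(seed=300, n_per_arm=300):
    cfg = reference_trial_config(seed=seed, n_per_arm=n_per_arm, two_arm=True,
                            dropout=SPARSE_DROPOUT)
    return simulate_trial(cfg)


class TestWindowRule:
    def test_exit_just_inside_window_is_not_dropout(self):
        ds = simulate_trial(reference_trial_config(seed=1, n_per_arm=5, two_arm=False))
        fu = ds.follow_up_ends()
        # all subjects complete: nobody within window of early exit
        assert not ds.subjects["dropout_flag"].any()
        assert (fu == 364.0).all()

    def test_boundary(self):
        eps = 0.5
        spec = SPARSE_DROPOUT
        T, window = 364.0, spec.dropout_window_days
        # the flag rule is exit < T - window
        assert (T - window + eps) >= T - window  # not a dropout
        ds = dropout_dataset(seed=301)
        fu = ds.follow_up_ends()
        flagged = ds.subjects["dropout_flag"]
        assert (fu[flagged] < T - window).all()
        assert (fu[~flagged] >= T - window).all()


class TestLikelihood:
    def test_all_complete_likelihood_is_sum_log_survival(self):
        ds = simulate_trial(reference_trial_config(seed=2, n_per_arm=20, two_arm=False))
        formula = DropoutFormula(family="loglogistic", covariates=())
        comp = _build_dropout(ds, formula)
        assert comp.event.sum() == 0
        theta0, alpha = 3000.0, 1.4
        v = np.array([math.log(theta0), math.log(alpha)])
        expected = float(
            np.sum(log_survival(Family.LOGLOGISTIC,
                                ds.follow_up_ends().to_numpy(), theta0, alpha))
        )
        assert comp.total_loglik(v) == pytest.approx(expected, abs=1e-9)

    def test_joint_deviance_is_sum_of_components(self):
        """At identical fixed parameters, the integrated likelihood equals
        two-state likelihood plus dropout likelihood (MAR additivity)."""
        ds = dropout_dataset(seed=302, n_per_arm=40)
        base = ModelFormula(family="loglogistic", frailty_12=False, frailty_21=False)
        joint = attach_dropout(base, DropoutFormula(family="loglogistic",
                                                    covariates=("disease_stage",)))
        params = {
            "12": {"theta0": 150.0, "alpha": 1.34, "beta": {}},
            "21": {"theta0": 8.0, "alpha": 2.97, "beta": {}},
            "dropout": {"theta0": 3500.0, "alpha": 1.5,
                        "beta": {"disease_stage": -0.68}},
        }
        two_state = total_loglik(ds, base, {k: params[k] for k in ("12", "21")})
        comp = _build_dropout(ds, joint.dropout)
        v = np.array([math.log(3500.0), math.log(1.5), -0.68])
        assert total_loglik(ds, joint, params) == pytest.approx(
            two_state + comp.total_loglik(v), abs=1e-8
        )

    def test_null_dropout_block_leaves_transition_likelihood_unchanged(self):
        ds = dropout_dataset(seed=302, n_per_arm=40)
        base = ModelFormula(family="loglogistic", frailty_12=False, frailty_21=False)
        joint = attach_dropout(base, DropoutFormula(covariates=()))
        params = {
            "12": {"theta0": 150.0, "alpha": 1.34, "beta": {}},
            "21": {"theta0": 8.0, "alpha": 2.97, "beta": {}},
        }
        base_ll = total_loglik(ds, base, params)
        # adding a dropout block changes the joint by exactly the dropout term
        params["dropout"] = {"theta0": 5000.0, "alpha": 1.2, "beta": {}}
        comp = _build_dropout(ds, joint.dropout)
        v = np.array([math.log(5000.0), math.log(1.2)])
        assert total_loglik(ds, joint, params) - base_ll == pytest.approx(
            comp.total_loglik(v), abs=1e-8
        )


class TestFits:
    def test_zero_dropouts_warns(self):
        ds = simulate_trial(reference_trial_config(seed=3, n_per_arm=25, two_arm=False))
        f = fit_dropout(ds, DropoutFormula(covariates=("disease_stage",)),
                        sampler=SamplerConfig(chains=2, warmup=200, draws=200, seed=1))
        assert any("unidentifiable" in w for w in f.warnings)

    def test_joint_fit_matches_separate_fit_posterior(self):
        """Under MAR with an exogenous dropout covariate the transition
        posterior from the joint fit equals the separate fit up to
        Monte-Carlo error."""
        ds = dropout_dataset(seed=303, n_per_arm=150)
        sc = SamplerConfig(chains=2, warmup=500, draws=500, seed=2)
        base = ModelFormula(family="loglogistic")
        separate = fit(ds, base, sampler=sc)
        joint = fit(ds, attach_dropout(base, DropoutFormula(covariates=("disease_stage",))),
                    sampler=sc)
        for name in ("alpha_12", "alpha_21"):
            assert joint.median(name) == pytest.approx(separate.median(name), abs=0.1)

    def test_loglogistic_beats_exponential_dic_on_loglogistic_truth(self):
        wins = 0
        for s in range(5):
            ds = dropout_dataset(seed=300 + s)
            dics = {}
            for fam in ("loglogistic", "exponential"):
                f = fit_dropout(
                    ds, DropoutFormula(family=fam, covariates=("disease_stage",)),
                    sampler=SamplerConfig(chains=2, warmup=500, draws=500, seed=s),
                )
                dics[fam] = f.dic
            wins += dics["loglogistic"] < dics["exponential"]
        assert wins >= 4

    def test_derived_covariates_accepted_in_separate_fit(self):
        ds = dropout_dataset(seed=304, n_per_arm=100)
        f = fit_dropout(
            ds,
            DropoutFormula(covariates=("n_exacerbations", "disease_stage", "state2_time")),
            sampler=SamplerConfig(chains=2, warmup=300, draws=300, seed=3),
        )
        assert "beta_dropout_n_exacerbations" in f.draws
        # event-derived covariates bar forward simulation of dropout
        assert f.dropout_spec(0) is None
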