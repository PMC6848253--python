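"""Likelihood assembly and MCMC: closed-form sojourn contributions,
additivity, a brute-force likelihood oracle, an exact conjugate-posterior
oracle for the sampler, prior recovery with no data, null-frailty recovery,
determinism and the DIC identities."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from copdsm import (
    Family,
    ModelFormula,
    SamplerConfig,
    SojournRecord,
    dic,
    fit,
    reference_trial_config,
    significant,
    simulate_trial,
    sojourn_loglik,
    total_loglik,
)
from copdsm.families import density, hazard, survival
from copdsm.inference import _Component, _run_chain, PriorConfig


class TestSojournLoglik:
    def test_exponential_event_closed_form(self):
        rec = SojournRecord("A", 1, 1, 2.0, True)
        assert sojourn_loglik(rec, 0.5, None, Family.EXPONENTIAL) == pytest.approx(
            math.log(0.5) - 1.0, abs=1e-12
        )

    def test_exponential_censored_closed_form(self):
        rec = SojournRecord("A", 1, 1, 2.0, False)
        assert sojourn_loglik(rec, 0.5, None, Family.EXPONENTIAL) == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "family,theta,alpha",
        [(Family.WEIBULL, 0.01, 1.7), (Family.GOMPERTZ, 0.02, -0.003),
         (Family.LOGLOGISTIC, 40.0, 1.34)],
    )
    def test_event_equals_log_density(self, family, theta, alpha):
        rec = SojournRecord("A", 1, 1, 17.0, True)
        assert sojourn_loglik(rec, theta, alpha, family) == pytest.approx(
            math.log(density(family, 17.0, theta, alpha)), abs=1e-10
        )


def _tiny_dataset(n=10, seed=123):
    cfg = reference_trial_config(seed=seed, n_per_arm=n, two_arm=True)
    return simulate_trial(cfg)


PARAMS = {
    "12": {"theta0": 120.0, "alpha": 1.3,
           "beta": {"log_study_length": 0.1, "treatment": 0.2}, "sigma2": 0.1},
    "21": {"theta0": 8.0, "alpha": 2.8, "beta": {}, "sigma2": 0.1},
}


class TestTotalLoglik:
    def test_singleton_equals_sojourn_loglik(self):
        ds = _tiny_dataset(n=2)
        one = ds.sojourns.iloc[[0]]
        sid = one["subject_id"].iloc[0]
        ds_one = type(ds)(ds.subjects.loc[[sid]], one, dropout_window=ds.dropout_window)
        formula = ModelFormula(family="loglogistic", frailty_12=False, frailty_21=False)
        params = {"12": {"theta0": 50.0, "alpha": 1.3, "beta": {}},
                  "21": {"theta0": 8.0, "alpha": 2.8, "beta": {}}}
        rec = SojournRecord(sid, 1, 1, float(one["duration"].iloc[0]),
                            bool(one["event"].iloc[0]))
        assert total_loglik(ds_one, formula, params) == pytest.approx(
            sojourn_loglik(rec, 50.0, 1.3, Family.LOGLOGISTIC), abs=1e-10
        )

    def test_doubling_dataset_doubles_loglik(self):
        ds = _tiny_dataset(n=6)
        formula = ModelFormula(family="loglogistic", frailty_12=False, frailty_21=False)
        params = {"12": {"theta0": 120.0, "alpha": 1.3, "beta": {}},
                  "21": {"theta0": 8.0, "alpha": 2.8, "beta": {}}}
        base = total_loglik(ds, formula, params)
        subj2 = ds.subjects.copy()
        subj2.index = [f"{s}_b" for s in subj2.index]
        soj2 = ds.sojourns.copy()
        soj2["subject_id"] = soj2["subject_id"] + "_b"
        doubled = type(ds)(
            pd.concat([ds.subjects, subj2]),
            pd.concat([ds.sojourns, soj2], ignore_index=True),
        )
        assert total_loglik(doubled, formula, params) == pytest.approx(2 * base, abs=1e-8)

    def test_matches_brute_force_row_loop(self):
        """Independent oracle: loop over rows with the family primitives and
        scipy's normal log-pdf for the frailty prior."""
        ds = _tiny_dataset(n=5)
        assert len(ds.sojourns) >= 20
        rng = np.random.default_rng(9)
        eta12 = {sid: float(rng.normal(0, 0.3)) for sid in ds.subject_ids}
        eta21 = {sid: float(rng.normal(0, 0.3)) for sid in ds.subject_ids}
        params = {
            "12": dict(PARAMS["12"], eta=eta12),
            "21": dict(PARAMS["21"], eta=eta21),
        }
        formula = ModelFormula(family="loglogistic")
        expected = 0.0
        for r in ds.sojourns.itertuples(index=False):
            p = params["12"] if r.state == 1 else params["21"]
            row = ds.subjects.loc[r.subject_id]
            lp = math.log(p["theta0"]) + p["eta"][r.subject_id]
            for name, coef in p["beta"].items():
                x = (math.log(row["study_length"]) if name == "log_study_length"
                     else row[name])
                lp += coef * x
            theta = math.exp(lp)
            fam = Family.LOGLOGISTIC
            contrib = math.log(survival(fam, r.duration, theta, p["alpha"]))
            if r.event:
                contrib += math.log(hazard(fam, r.duration, theta, p["alpha"]))
            expected += contrib
        for p in params.values():
            for sid in ds.subject_ids:
                expected += stats.norm.logpdf(p["eta"][sid], 0, math.sqrt(p["sigma2"]))
        assert total_loglik(ds, formula, params) == pytest.approx(expected, abs=1e-10)

    def test_domain_violation_returns_neg_inf(self):
        ds = _tiny_dataset(n=3)
        formula = ModelFormula(family="loglogistic", frailty_12=False, frailty_21=False)
        params = {"12": {"theta0": -1.0, "alpha": 1.3, "beta": {}},
                  "21": {"theta0": 8.0, "alpha": 2.8, "beta": {}}}
        assert total_loglik(ds, formula, params) == -np.inf


class TestSamplerOracles:
    def test_exponential_posterior_matches_conjugate_gamma(self):
        """With a flat-in-log prior (normal(0,1000) on log theta) the
        exponential-rate posterior is Gamma(events, exposure) exactly."""
        cfg = reference_trial_config(seed=77, n_per_arm=150, two_arm=False,
                                family="exponential", sigma2=0.0)
        ds = simulate_trial(cfg)
        f = fit(
            ds,
            ModelFormula(family="exponential", frailty_12=False, frailty_21=False),
            sampler=SamplerConfig(chains=2, warmup=500, draws=1000, seed=3),
        )
        s1 = ds.sojourns[ds.sojourns["state"] == 1]
        events = int(s1["event"].sum())
        exposure = float(s1["duration"].sum())
        oracle = stats.gamma(a=events, scale=1 / exposure)
        draws = f.flat("theta0_12")
        assert np.mean(draws) == pytest.approx(oracle.mean(), rel=0.02)
        assert np.std(draws) == pytest.approx(oracle.std(), rel=0.15)
        lo, hi = f.ci("theta0_12")
        assert lo == pytest.approx(oracle.ppf(0.025), rel=0.05)
        assert hi == pytest.approx(oracle.ppf(0.975), rel=0.05)

    def test_no_data_returns_the_prior(self):
        """A component with zero records leaves the posterior equal to the
        prior normal(0, 1000) on the unconstrained parameters."""
        comp = _Component(
            name="12", family=Family.WEIBULL, t=np.array([]),
            event=np.array([], dtype=bool), X=np.zeros((0, 0)), coef_names=[],
            subj=np.array([], dtype=np.intp), n_subjects=1, frailty=False,
            shape_frailty=False, logT_center=0.0,
        )
        rng = np.random.default_rng(5)
        out_v, _, _, _ = _run_chain({"12": comp}, PriorConfig(), 2000, 10000, rng)
        draws = out_v["12"][:, 0]
        sd = math.sqrt(1000.0)
        assert abs(np.mean(draws)) < 4 * sd / math.sqrt(200)  # ESS-conservative
        assert np.std(draws) == pytest.approx(sd, rel=0.15)


class TestFitContract:
    def test_determinism_same_seed_same_draws(self):
        ds = _tiny_dataset(n=8)
        sc = SamplerConfig(chains=2, warmup=100, draws=100, seed=4)
        f1 = fit(ds, ModelFormula(family="loglogistic"), sampler=sc)
        f2 = fit(ds, ModelFormula(family="loglogistic"), sampler=sc)
        for k in f1.draws:
            np.testing.assert_array_equal(f1.draws[k], f2.draws[k])

    def test_null_frailty_concentrates_near_zero(self):
        cfg = reference_trial_config(seed=78, n_per_arm=200, two_arm=False, sigma2=0.0)
        ds = simulate_trial(cfg)
        f = fit(ds, ModelFormula(family="loglogistic"),
                sampler=SamplerConfig(chains=2, warmup=600, draws=600, seed=5))
        assert f.median("sigma2_12") < 0.05
        assert f.median("sigma2_21") < 0.05

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelFormula(family="loglogistic", covariates_12=("bmi",))

    def test_significance_rule_is_ci_excludes_zero(self, two_arm_exp_fit):
        lo, hi = two_arm_exp_fit.ci("beta_12_treatment")
        assert significant(two_arm_exp_fit, "beta_12_treatment") == (lo > 0 or hi < 0)


class TestDIC:
    def test_identity_and_permutation_invariance(self, small_fit):
        d, p_d = dic(small_fit)
        dbar = float(small_fit.deviance.mean())
        assert d == pytest.approx(dbar + p_d, abs=1e-9)
        # Dbar (hence DIC at fixed plug-in) ignores draw order
        perm = np.random.default_rng(0).permutation(small_fit.deviance.reshape(-1))
        assert perm.mean() == pytest.approx(dbar, abs=1e-9)

    def test_deviance_trace_matches_fixed_parameter_likelihood(self, small_dataset, small_fit):
        """The stored deviance at a draw equals -2x the data log-likelihood
        recomputed at that draw's natural-scale parameters and frailties."""
        f = small_fit
        i = 37  # arbitrary flattened draw
        chain, j = divmod(i, f.n_draws)
        params = {}
        for direction, key in (("1->2", "12"), ("2->1", "21")):
            spec = f.transition_spec(direction, i)
            eta = f.eta_draws[key][chain, j]
            params[key] = {
                "theta0": spec.theta0, "alpha": spec.alpha, "beta": spec.beta,
                "eta": dict(zip(f.subject_ids, eta)),
            }
        ll = total_loglik(small_dataset, f.formula, params)
        assert -2.0 * ll == pytest.approx(f.deviance[chain, j], rel=1e-8)
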