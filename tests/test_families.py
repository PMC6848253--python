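"""Closed-form kernels of the four sojourn-time families and the
covariate/frailty link: printed-formula values, distributional identities,
reductions between families, and cross-checks against scipy.stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from copdsm import (
    Family,
    SubjectCovariates,
    TransitionSpec,
    density,
    hazard,
    link_subject_params,
    quantile,
    survival,
)

FAMILIES = [
    (Family.EXPONENTIAL, 0.05, None),
    (Family.WEIBULL, 0.01, 1.6),
    (Family.GOMPERTZ, 0.02, 0.004),
    (Family.GOMPERTZ, 0.02, -0.002),
    (Family.LOGLOGISTIC, 40.0, 1.34),
]


class TestPointValues:
    def test_exponential_hazard_is_constant(self):
        for t in (0.5, 3.0, 100.0):
            assert hazard(Family.EXPONENTIAL, t, 0.5) == 0.5

    def test_weibull_shape_one_reduces_to_exponential(self):
        t = np.array([0.3, 3.0, 50.0, 400.0])
        np.testing.assert_array_equal(
            hazard(Family.WEIBULL, t, 0.5, 1.0), hazard(Family.EXPONENTIAL, t, 0.5)
        )
        np.testing.assert_array_equal(
            survival(Family.WEIBULL, t, 0.5, 1.0), survival(Family.EXPONENTIAL, t, 0.5)
        )

    def test_loglogistic_hazard_at_scale(self):
        # at t = theta the log-logistic hazard equals alpha / (2 theta)
        assert hazard(Family.LOGLOGISTIC, 10.0, 10.0, 2.0) == pytest.approx(0.1, rel=1e-12)

    def test_loglogistic_survival_at_scale_is_half(self):
        for alpha in (0.7, 1.34, 5.0):
            assert survival(Family.LOGLOGISTIC, 7.0, 7.0, alpha) == pytest.approx(0.5)

    def test_weibull_survival_closed_form(self):
        # exp(-theta t^alpha) = e^-1 at theta=0.01, alpha=2, t=10
        assert survival(Family.WEIBULL, 10.0, 0.01, 2.0) == pytest.approx(
            math.exp(-1.0), rel=1e-9
        )

    def test_gompertz_small_shape_limits_to_exponential(self):
        assert survival(Family.GOMPERTZ, 2.0, 0.5, 1e-8) == pytest.approx(
            math.exp(-1.0), abs=1e-6
        )

    def test_gompertz_negative_shape_is_defective(self):
        # S(t) -> exp(theta/alpha) > 0: some subjects never transition
        theta, alpha = 0.01, -0.02
        assert survival(Family.GOMPERTZ, 1e6, theta, alpha) == pytest.approx(
            math.exp(theta / alpha), rel=1e-9
        )


class TestQuantile:
    def test_loglogistic_median_is_scale(self):
        assert quantile(Family.LOGLOGISTIC, 0.5, 7.0, 3.0) == pytest.approx(7.0)

    def test_exponential_quantile_closed_form(self):
        assert quantile(Family.EXPONENTIAL, 1 - math.exp(-1), 0.5) == pytest.approx(2.0)

    @pytest.mark.parametrize("family,theta,alpha", FAMILIES)
    def test_survival_quantile_roundtrip(self, family, theta, alpha):
        u = np.array([0.001, 0.1, 0.5, 0.9, 0.999])
        t = quantile(family, u, theta, alpha)
        np.testing.assert_allclose(1 - survival(family, t, theta, alpha), u, rtol=1e-8)

    def test_quantile_domain_error(self):
        with pytest.raises(ValueError, match="u"):
            quantile(Family.WEIBULL, 1.5, 0.1, 2.0)


class TestDistributionIdentities:
    @pytest.mark.parametrize("family,theta,alpha", FAMILIES[:3] + FAMILIES[4:])
    def test_density_integrates_to_one(self, family, theta, alpha):
        # defective (negative-shape Gompertz) excluded: its mass is < 1
        val, err = integrate.quad(
            lambda t: density(family, t, theta, alpha), 0, np.inf, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("family,theta,alpha", FAMILIES)
    def test_survival_equals_exp_integrated_hazard(self, family, theta, alpha):
        for t in (0.1, 1.0, 20.0, 150.0, 500.0):
            cum, _ = integrate.quad(lambda u: hazard(family, u, theta, alpha), 0, t, limit=200)
            assert survival(family, t, theta, alpha) == pytest.approx(
                math.exp(-cum), abs=1e-6
            )

    @pytest.mark.parametrize("family,theta,alpha", FAMILIES)
    def test_density_is_hazard_times_survival(self, family, theta, alpha):
        t = np.array([0.5, 5.0, 60.0, 300.0])
        np.testing.assert_allclose(
            density(family, t, theta, alpha),
            hazard(family, t, theta, alpha) * survival(family, t, theta, alpha),
            rtol=1e-12,
        )


class TestScipyCrossChecks:
    """scipy.stats carries the same distributions under different
    parameterisations; agreement pins down ours."""

    def test_exponential(self):
        t = np.array([1.0, 30.0, 200.0])
        np.testing.assert_allclose(
            survival(Family.EXPONENTIAL, t, 0.02), stats.expon.sf(t, scale=50.0)
        )

    def test_weibull(self):
        theta, alpha = 0.01, 1.7  # S = exp(-theta t^alpha) -> scale = theta^(-1/alpha)
        t = np.array([1.0, 10.0, 40.0])
        np.testing.assert_allclose(
            survival(Family.WEIBULL, t, theta, alpha),
            stats.weibull_min.sf(t, alpha, scale=theta ** (-1 / alpha)),
            rtol=1e-10,
        )

    def test_loglogistic_is_fisk(self):
        theta, alpha = 40.0, 1.34
        t = np.array([1.0, 40.0, 300.0])
        np.testing.assert_allclose(
            survival(Family.LOGLOGISTIC, t, theta, alpha),
            stats.fisk.sf(t, alpha, scale=theta),
            rtol=1e-10,
        )
        np.testing.assert_allclose(
            density(Family.LOGLOGISTIC, t, theta, alpha),
            stats.fisk.pdf(t, alpha, scale=theta),
            rtol=1e-10,
        )

    def test_gompertz_positive_shape(self):
        theta, alpha = 0.02, 0.01  # scipy: S = exp(-c (e^(t/scale) - 1))
        t = np.array([1.0, 20.0, 100.0])
        np.testing.assert_allclose(
            survival(Family.GOMPERTZ, t, theta, alpha),
            stats.gompertz.sf(t, theta / alpha, scale=1 / alpha),
            rtol=1e-10,
        )


class TestLink:
    def test_identity_link(self):
        spec = TransitionSpec(1, Family.LOGLOGISTIC, theta0=0.02, alpha=1.3)
        cov = SubjectCovariates(study_length=364)
        theta, alpha = link_subject_params(spec, cov, eta=0.0)
        assert theta == pytest.approx(0.02)
        assert alpha == 1.3

    def test_stage_coefficient_shrinks_scale(self):
        # beta_stage = -0.40 on a stage-1 subject: theta = 0.02 e^-0.40
        spec = TransitionSpec(
            1, Family.LOGLOGISTIC, theta0=0.02, alpha=1.3,
            beta={"disease_stage": -0.40},
        )
        cov = SubjectCovariates(disease_stage=1)
        theta, _ = link_subject_params(spec, cov, eta=0.0)
        assert theta == pytest.approx(0.0134064, rel=1e-5)

    def test_frailty_multiplies_scale(self):
        spec = TransitionSpec(1, Family.WEIBULL, theta0=0.02, alpha=1.0)
        theta, _ = link_subject_params(spec, SubjectCovariates(), eta=0.3)
        assert theta == pytest.approx(0.02 * math.exp(0.3), rel=1e-9)
        assert theta == pytest.approx(0.0269972, rel=1e-5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        eta=st.floats(-2, 2),
        b0=st.floats(-1, 1),
        b1=st.floats(-1, 1),
        stage=st.integers(0, 1),
    )
    def test_log_theta_is_additive(self, eta, b0, b1, stage):
        spec = TransitionSpec(
            1, Family.LOGLOGISTIC, theta0=50.0, alpha=1.3,
            beta={"log_study_length": b0, "disease_stage": b1},
        )
        cov = SubjectCovariates(disease_stage=stage, study_length=200.0)
        theta, _ = link_subject_params(spec, cov, eta=eta)
        expected = math.log(50.0) + eta + b0 * math.log(200.0) + b1 * stage
        assert math.log(theta) == pytest.approx(expected, abs=1e-10)
        assert theta > 0

    def test_domain_errors_name_offender(self):
        with pytest.raises(ValueError, match="theta"):
            hazard(Family.WEIBULL, 1.0, -0.1, 2.0)
        with pytest.raises(ValueError, match="alpha"):
            hazard(Family.LOGLOGISTIC, 1.0, 1.0, -2.0)
        with pytest.raises(ValueError, match="t"):
            hazard(Family.EXPONENTIAL, -1.0, 1.0)
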