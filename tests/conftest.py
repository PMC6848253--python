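import numpy as np
import pytest

from copdsm import (
    ModelFormula,
    SamplerConfig,
    fit,
    reference_trial_config,
    simulate_trial,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One-arm reference-scenario trial, small enough for fast MCMC in tests."""
    cfg = reference_trial_config(seed=42, n_per_arm=60, two_arm=False)
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    return fit(
        small_dataset,
        ModelFormula(family="loglogistic"),
        sampler=SamplerConfig(chains=2, warmup=400, draws=400, seed=7),
    )


@pytest.fixture(scope="session")
def two_arm_exp_dataset():
    """Two-arm exponential trial with a strong simulated drug effect."""
    cfg = reference_trial_config(
        seed=43, n_per_arm=80, two_arm=True, family="exponential",
        treatment_beta_12=-0.5, sigma2=0.0,
    )
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def two_arm_exp_fit(two_arm_exp_dataset):
    return fit(
        two_arm_exp_dataset,
        ModelFormula(
            family="exponential",
            covariates_12=("treatment",),
            frailty_12=False,
            frailty_21=False,
        ),
        sampler=SamplerConfig(chains=2, warmup=400, draws=400, seed=8),
    )
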