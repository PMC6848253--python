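"""Fit the parametric dropout model separately, then integrate it with the
two-state model (missing-at-random factorisation)."""

from copdsm import (
    DropoutFormula,
    DropoutSpec,
    ModelFormula,
    SamplerConfig,
    attach_dropout,
    fit,
    fit_dropout,
    reference_trial_config,
    simulate_trial,
)

dropout_truth = DropoutSpec(family="loglogistic", theta0=3500.0, alpha=1.5,
                            beta={"disease_stage": -0.68})
trial = simulate_trial(reference_trial_config(seed=3, n_per_arm=300, two_arm=True,
                                         dropout=dropout_truth))
print(f"observed dropout: {100 * trial.subjects.dropout_flag.mean():.1f}% "
      f"({int(trial.subjects.dropout_flag.sum())} of {trial.n_subjects})")

sampler = SamplerConfig(chains=2, warmup=800, draws=800, seed=3)
separate = fit_dropout(
    trial, DropoutFormula(family="loglogistic", covariates=("disease_stage",)),
    sampler=sampler,
)
med = separate.median("beta_dropout_disease_stage")
lo, hi = separate.ci("beta_dropout_disease_stage")
print(f"stage coefficient: {med:.2f} (95% CI {lo:.2f}, {hi:.2f}); truth -0.68")
print(f"dropout DIC: {separate.dic:.1f}")

joint_formula = attach_dropout(
    ModelFormula(family="loglogistic"),
    DropoutFormula(family="loglogistic", covariates=("disease_stage",)),
)
joint = fit(trial, joint_formula, sampler=sampler)
print(f"\nintegrated model DIC: {joint.dic:.1f} "
      f"(two-state + dropout blocks sampled jointly)")
print(f"alpha_12 from joint fit: {joint.median('alpha_12'):.2f} (truth 1.34)")
# Under MAR the likelihood factorises, so the transition-parameter posterior
# from the joint fit matches the separate fit up to Monte-Carlo error.
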