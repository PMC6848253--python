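"""Simulate a synthetic COPD exacerbation trial and describe it.

Subjects alternate between an asymptomatic state (1) and a symptomatic
exacerbation state (2); sojourn times are log-logistic with shapes 1.34 and
2.97 and subject-level frailty on the scales.
"""

from copdsm import reference_trial_config, simulate_trial, write_trial

config = reference_trial_config(seed=1, n_per_arm=150, two_arm=True,
                           treatment_beta_12=0.31)
trial = simulate_trial(config)

counts = trial.n_exacerbations()
print(f"subjects:               {trial.n_subjects}")
print(f"sojourn records:        {len(trial.sojourns)}")
print(f"mean exacerbations/yr:  {counts.mean():.2f}  (placebo "
      f"{counts[trial.subjects.treatment == 0].mean():.2f}, active "
      f"{counts[trial.subjects.treatment == 1].mean():.2f})")
print(f"mean days in state 2:   {trial.state_time(2).mean():.1f}")

write_trial(trial, "scratch_trial.csv")
print("wrote scratch_trial.csv (long format, one row per sojourn)")
# The placebo arm accumulates more exacerbations because the positive
# treatment coefficient enlarges the asymptomatic-state scale (longer
# symptom-free sojourns) in the active arm.
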