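# Paper-like 52-week two-arm scenario for the copdsm CLI:
#   copdsm simulate --config examples/reference_trial.yaml --out trial.csv
#   copdsm fit --data trial.csv --config examples/reference_trial.yaml --out fitdir
#   copdsm run --config examples/reference_trial.yaml --stages "simulate fit diagnose" --out rundir
simulation:
  family: loglogistic
  n_per_arm: 150
  two_arm: true
  study_length: 364.0
  theta1: 150.0       # asymptomatic-state scale, days
  alpha1: 1.34        # asymptomatic-state shape
  sigma2_1: 0.1       # frailty variance on the 1->2 scale
  theta2: 8.0         # symptomatic-state scale, days
  alpha2: 2.97
  sigma2_2: 0.1
  beta_1:
    treatment: 0.31   # active arm delays exacerbation onset
  dropout: null
  seed: 0
model:
  family: loglogistic
  covariates_12: [treatment]
  frailty: true
sampler:
  chains: 2
  warmup: 800
  draws: 800
  seed: 0
diagnostics:
  replicates: 100
  k_max: 8
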