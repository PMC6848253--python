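# Methods

## Model

Each subject's event history is an alternating renewal (two-state
semi-Markov) process: state 1 is asymptomatic, state 2 is a symptomatic
exacerbation, every history starts in state 1 at day 0, and the hazard of
leaving a state depends on the time since entering it. Four sojourn-time
families are implemented with hazard h, survival S = exp(−∫h) and density
f = h·S:

| family | h(t) | S(t) | shape domain |
|---|---|---|---|
| exponential | θ | e^{−θt} | — |
| Weibull | θαt^{α−1} | e^{−θt^α} | α > 0 |
| Gompertz | θe^{αt} | e^{(θ/α)(1−e^{αt})} | α ∈ ℝ |
| log-logistic | α(t/θ)^α / (t(1+(t/θ)^α)) | 1/(1+(t/θ)^α) | α > 0 |

θ > 0 is the scale (for the log-logistic it is the median sojourn in days; a
rate-like per-day^α quantity otherwise). A negative Gompertz shape gives a
defective distribution — mass exp(θ/α) never transitions — which the
quantile function reports as ∞ and the simulator treats as "censored at end
of follow-up". Near α = 0 the Gompertz log-survival is evaluated with
`expm1` and switches to the exact exponential limit below |α| = 1e−12.

Covariates and heterogeneity act log-linearly on the scale:

θ_kj = θ0_k · exp(η_kj) · exp(β_k0 log T_j + Σ_w β_kw x_jw),  η_kj ~ N(0, σ²_k).

Two points were genuinely open and are resolved as package conventions:

- **Frailty enters as exp(η) with normal η.** A normal multiplier applied
  directly to θ could be negative; the log-normal multiplier preserves
  positivity and makes the frailty one more additive term in the log-linear
  predictor.
- **Frailty acts on the scale only** by default. A switch
  (`ModelFormula.shape_frailty`) additionally multiplies the shape by
  exp(η), but exploratory fits in the motivating analyses supported a
  random effect on the scale alone, so it is off by default.

Time is measured in days throughout.

## Likelihood, priors, sampling

A completed sojourn of length t contributes log h + log S; a right-censored
one log S. Sojourns of a direction are conditionally independent across
subjects given (θ0, α, β, η). The dropout submodel is a parametric
time-to-event block (exponential, Weibull or log-logistic) on the subject's
follow-up end, with "dropout" defined by the window rule: the exit must
precede the nominal study end by more than the dropout window (30 days by
default; 14 for short-study analyses). Under the missing-at-random
assumption the integrated likelihood is the sum of the two blocks, so the
transition posterior is unaffected by attaching dropout; event-derived
dropout covariates (number of exacerbations, days in state 2) are treated as
fixed observed covariates, exactly as a separate conditional fit implies,
and bar forward simulation of the dropout process (which would break MAR).

Priors are vague: N(0, 1000) on each coefficient and on the unconstrained
transform of each positive parameter (log θ0; log α for Weibull/log-logistic;
raw α for Gompertz), and τ_k = 1/σ²_k ~ gamma(0.001, 0.001). Placing the
normal prior on the log scale rather than truncating a normal on the natural
scale is a deliberate divergence recorded as such: both are vague, but the
transform keeps the sampler unconstrained.

Sampling is Metropolis-within-Gibbs, chosen because the per-subject frailty
vector (hundreds of dimensions) is conditionally independent across subjects:

1. an adaptive random-walk Metropolis block per component (direction or
   dropout) on the unconstrained globals, with Haario-style covariance
   adaptation and Robbins–Monro scale tuning during warmup only;
2. a vectorised per-subject Metropolis update of η with per-subject step
   sizes adapted to 44% acceptance (two sweeps per iteration);
3. a conjugate Gibbs draw of τ_k;
4. an interweaved non-centred update of log σ (holding η/σ fixed), which
   rescales the whole frailty vector in one move — without it the
   frailty-spread/variance ridge mixes an order of magnitude slower;
5. a likelihood-invariant translation move (η → η + c, log θ0 → log θ0 − c)
   that removes the frailty-mean/intercept confounding.

Coefficients whose design column is identically zero (notably the centred
log-study-length column in a fixed-length design) are conditionally
independent of the data and are drawn directly from their prior.

The log-study-length column is centred before sampling (the reported
`theta0_*` is therefore referenced to the geometric-mean study length, and
`beta_*_log_study_length` is unchanged by the centring). With a single study
length the raw column would put an exact ridge between log θ0 and β_k0 under
vague priors. When a fitted model is used to simulate a design whose length
differs from the fitted one (extrapolation), the study-length term is frozen
at the fitted design length rather than extrapolated — with one study length
that coefficient is prior-driven and extrapolating it is meaningless.

Initial values are moment-based (crude rate or median of completed sojourns)
with per-chain jitter; chains are seeded by spawning a `SeedSequence` from
the user seed, so every fit is exactly reproducible. Convergence is
summarised by split-R̂ and effective sample size (arviz) on the global
parameters; R̂ > 1.05 records a warning on the fit rather than raising.

**DIC.** The deviance trace is the conditional deviance
−2 log p(data | globals, η) per draw; DIC = D̄ + pD with
pD = D̄ − D(posterior means of the unconstrained globals and frailties).
This is the classic conditional-DIC construction; its known sensitivities
apply — pD counts the frailties, can exceed the nominal parameter count, and
rewards subject-level adaptation. One measured consequence: on synthetic
log-logistic data with frailty variance 0.1, a Weibull fit with a larger
fitted frailty variance attains conditional DIC within a few points of (often
below) the log-logistic fit, because a log-normal mixture of Weibulls mimics
a log-logistic marginal and ~1.5 completed sojourns per subject and state
carry little within-subject shape information. With frailty absent (from
truth and fit) the log-logistic model wins by ~70 points at n = 300, and the
exponential and Gompertz fits always lose heavily; family discrimination
against the Weibull under strong frailty should not be expected from
conditional DIC at these sizes. Ties (ΔDIC < 2) should be read as ties.

## Synthetic trials

The generator is the study-design description, not a tuning knob. The
default reference scenario is a 52-week (364-day) trial with log-logistic
transitions: shapes 1.34 (onset) and 2.97 (resolution) taken from the fitted
medians, scales θ1 = 150 d and θ2 = 8 d calibrated once by simulation so the
mean annual exacerbation count is ≈ 1.5 (the entry criterion of the
motivating trials was at least one exacerbation per year) with ~10-day
exacerbations, and frailty σ² = 0.1 on both scales. The naive renewal
approximation T/μ undershoots the count here because the α < 2 log-logistic
has infinite variance; calibration was done at n = 2000. The Weibull variant
uses shapes 1.004/1.75 with scales matched to the same annual rate. Binary
covariates (disease stage, smoking, season) are Bernoulli(0.5); pack-years
are gamma with mean 45 and SD 18. The sparse dropout scenario is
log-logistic with θ = 3500 d, α = 1.5 and stage coefficient −0.68, giving
~5% dropout over 52 weeks.

Sojourns are drawn by inverse-CDF sampling, alternating states until
follow-up min(T_j, dropout time) is exhausted; the open sojourn is censored.
Completed sojourns are floored at 0.5 day (daily-granularity convention;
log h diverges at t → 0 for some shapes). Dropout is drawn independently of
the event process (MAR). All draws flow through one seeded generator;
diagnostic replicate r uses seed base + r.

What the generator does *not* emulate — and hence what passing recovery
tests do not establish about real trials: seasonal/time-varying hazards,
treatment switching or non-adherence, informative (MNAR) dropout, covariate
correlation structure, and recording artefacts of real visit schedules
(interval censoring, same-day onset/resolution). It generates data exactly
from the fitted model class, so recovery results speak to the correctness
and calibration of the inference machinery, not to model adequacy for any
real dataset.

## Diagnostics, effects, design

PPC: for each replicate, a posterior draw is taken, a trial with the
observed design (same subjects, covariates, study lengths; fresh frailties
from the drawn σ²) is simulated, and scalar statistics — total records,
records per state, total exacerbations, dropout count — are compared with
the observed values via the upper-tail probability P(T_rep ≥ T_obs). VPC:
completed sojourn durations per state are binned; bin counts are compared
with the replicates' 2.5–97.5% interval, as is the per-subject
exacerbation-count histogram. The bin count is chosen by running 1-D k-means
for k = 1..k_max (10 restarts, fixed seed, raw durations) and taking the
elbow — the largest second difference of the within-cluster sum of squares —
with a manual override; bin edges are midpoints between adjacent cluster
centres. The automatic elbow rule is a package decision (the source analyses
read the elbow off a plot).

Drug effects are summarised by the transition-rate ratio
h_ref(t)/h_alt(t) (default placebo/active; > 1 on the onset direction means
the drug delays exacerbations) and the transition probability F(t) = 1 − S(t)
under a covariate stratum, both as pointwise posterior medians with 95%
bands. Curves are typical-subject curves: frailty is fixed at its median
(0 on the log scale) rather than integrated, and the study-length term is
held at the design length so it cancels in ratios. The default grid is 1-day
steps over (0, T].

Design exploration subsamples subjects per arm without replacement and/or
truncates follow-up at L days (re-censoring sojourns that cross L and
recomputing dropout flags under the window rule), refits, and reports the
rate-ratio curve with a significance verdict (95% band excludes 1 anywhere
on the grid). Extrapolation fits on truncated data, simulates replicate
trials to a longer horizon, and compares the predicted exacerbation-count
distribution with data observed over that horizon; interval widths grow with
the horizon.

## Numerical conventions and edge cases

- Zero-length sojourns are rejected; completed sojourns must be ≥ 0.5 day.
  Only the final sojourn per subject may be censored, and histories must
  alternate starting from state 1 — violations are reported with the
  offending subject.
- Out-of-domain proposals in the sampler evaluate to −∞ and are rejected;
  `total_loglik` returns −∞ for domain violations (sampler-safe contract).
- Percentile summaries use linear interpolation, so exactly-inverse curves
  (ratio reciprocity) agree to interpolation error (~1e−4), while the
  underlying per-draw values are exactly reciprocal.
- Problem sizes in the test suite: recovery checks run one arm of 150
  subjects (the motivating design), coverage loops 20 refits at 2 chains ×
  1500 draws, effect-recovery checks 5 refits of 2×150 subjects, the DIC
  comparison 5 datasets of 300 subjects, and diagnostics fixtures 60–80
  subjects; these sizes keep full-suite runtime modest while leaving
  Monte-Carlo margins well inside the asserted tolerances.

## Known limitations

- Conditional DIC's weak penalty on frailty-absorbed misfit (above).
- One family per fit across both directions by default (mixed per-state
  families are a natural extension hook, as is correlated multivariate
  frailty between directions; both are deliberately out of scope).
- No time-varying covariates; seasonality enters only as a baseline binary.
- The sampler is random-walk based: posteriors with strong curvature (e.g.
  near-zero frailty variance) mix more slowly than gradient-based samplers
  would; the interweaved moves mitigate the worst ridges, and R̂/ESS are
  always reported.
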