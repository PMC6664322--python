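# Methods

This note documents the models, estimators, generative assumptions and
numerical choices behind the package, and what the simulation-based tests
do and do not establish.

## Task environment

The two-step environment is parameterised by `TaskConfig`: 67 trials per
session, a fixed transition structure in which each stage-1 action reaches
its common stage-2 state with probability 0.7 (rare 0.3), binary reward
drawn Bernoulli from per-option probabilities, and trial timing (2.22 s
stage displays, 1.11 s outcome, 0.8 s ISI, ITI uniform on [0, 3.6] s,
mean 1.8 s). Reward probabilities for the four stage-2 options evolve as
independent Gaussian random walks (step SD 0.025) **reflected** into
[0.25, 0.75]; reflection rather than clamping keeps the stationary
distribution off the boundaries. Three walk sets are derived from fixed
sub-seeds of the master seed and sessions are assigned one of them. The
transition probabilities, walk SD and bounds follow the conventional design
of this task family; all are configurable because no single canonical value
exists.

## Hybrid controller and likelihood

Stage-2 values `Q₂(s,a)` learn by `δ₂ = r − Q₂`; the stage-1 model-free
values learn by `δ₁ = Q₂(s₂,a₂) − Q_MF(a₁)` plus the eligibility-weighted
stage-2 error (`α₁λδ₂`). Model-based stage-1 values are recomputed each
trial from the *true, fixed* transition matrix (transition learning is out
of scope). Choice probabilities are softmax with inverse temperatures β₁
(applied to the w-blended value, plus the perseveration bonus outside the
blend) and β₂. Conventions:

- Q values initialise to 0 (0.5 available via `q_init` for sensitivity
  checks); reward is coded {0,1} with no separate scaling parameter.
- Perseveration applies at stage 1 only and is keyed to the last *valid*
  stage-1 choice.
- Invalid (missed-deadline) trials contribute no likelihood and trigger no
  update.
- Choice probabilities are floored at 1e−12 inside the log so the
  objective stays finite everywhere (`PROB_FLOOR`).

The likelihood is chain-rule exact: summed over all choice sequences of a
fixed state/reward path it integrates to 1, which the tests verify by
enumeration to 1e−10. A numba-compiled array kernel is used for fitting; a
pure-Python reference implementation of the same recursion is kept and the
two are held to 1e−8 agreement in the tests.

## Estimation

Per subject × condition session (matching the study design), maximum
likelihood on an unconstrained reparameterisation: log for β₁, β₂, logit
for α₁, α₂, λ, w, identity for perseveration; bound values are clipped
inward by 1e−6 before transforming. Ten random restarts by default, drawn
uniform from a documented box (log-β in [−1, 2.5], logits in [−2, 2],
perseveration in [−1, 1]), each optimised with L-BFGS-B (gradient by finite
differences, objective tolerance 1e−6); the best restart is returned with a
convergence flag. Standard errors are delta-method transforms of the
inverse numerical Hessian in unconstrained space; they are reported as
approximate and become NaN when the Hessian is singular (common when a
parameter sits at a bound). No priors are used by default; this is plain
MLE. A ridge-like MAP option (`map_prior_sd`) adds a Gaussian penalty on
the unconstrained parameters for regularised sensitivity analyses; the
reported log-likelihood is always the unpenalised one, flagged by the fit
configuration.

Known property, quantified by the recovery study rather than assumed: at
67 trials the MLE of w is noisy and shrinks group differences. With
favourable parameters (β = 5, α = 0.7) recovery of w at 67 trials reaches
r ≈ 0.8 with slope ≈ 0.8; under the heterogeneous cohort population below
it drops to r ≈ 0.5, and an injected +0.2 shift of true w appears as
roughly +0.10 in fitted w. Cohort-level power calculations must use fitted,
not true, effect sizes.

## Working-memory precision

Orientations are undirected lines (period π). The signed error wraps
response − target into (−π/2, π/2] (the boundary maps to +π/2). Errors are
doubled onto the full circle; the circular SD is `sqrt(−2 ln R)/2` with R
the resultant length, so precision = 1/SD is in rad⁻¹. A linear option
(ordinary SD of the wrapped errors) exists for sensitivity checks; the two
agree closely for concentrated errors and diverge as responses approach
uniformity. Degenerate cases:
R below 1e−12 (uniform responding) reports the documented maximum SD
(`MAX_CIRCULAR_SD` ≈ 3.72 rad) with a flag; SD = 0 yields *missing*
precision, never infinity, so downstream ANOVAs stay finite. Precision is
uncorrected by default ("reciprocal of the SD"); an optional
permutation-based chance correction (responses shuffled across trials, 200
permutations) can be subtracted and is flagged in every output. Log
precision (natural log) is the ANOVA outcome.

## Statistical battery

- Normality: Kolmogorov–Smirnov with Lilliefors correction (parameters
  estimated from the sample).
- RM-ANOVA: pingouin behind the module surface; one or two within factors;
  a between-subjects *order* factor (day of control stimulation, 3 levels)
  yields the order × condition interaction. The 2-within + between design
  is not offered; the load × stimulation analysis runs as a 2 × 3
  within-subjects model.
- Paired contrasts report the t statistic with *both* effect-size
  conventions, `r_t = sqrt(t²/(t²+df))` and `r_z = |Z|/√(2n)` from the
  matching rank test, because the two conventions disagree in published
  usage and neither is canonical; a Bonferroni-style corrected alpha of
  .025 for the two planned contrasts is carried in the flags.
- Wilcoxon signed-rank: zeros dropped, ties mid-ranked; exact two-tailed p
  by full sign enumeration (computed as a convolution over doubled
  mid-ranks) for ≤ 20 nonzero differences, else a normal approximation with
  continuity and tie corrections.
- Rank ANCOVA: rank-transform procedure — the outcome is ranked across all
  observations and the order-adjusted mixed model is applied to the ranks.
  Degrees of freedom follow that decomposition and are reported with the
  result; other published df conventions for ranked ANCOVA exist. Quade's
  blocked rank test is available as an alternative (no covariate
  adjustment), validated against R's `quade.test`.
- ICC(3,k): two-way mixed, consistency, average measures, computed from the
  ANOVA decomposition `(MS_subjects − MS_error)/MS_subjects` with its F
  test.
- Bayesian correlation: log BF₁₀ by numerical integration (scipy `quad`) of
  the exact sampling density of r (hypergeometric form) against the
  stretched-beta width-1 (uniform) prior on ρ.
- Power: two-tailed paired t from the noncentral t distribution; the
  sample-size solver scans n upward.
- Behavioural signatures: stay probabilities over consecutive valid trial
  pairs in a 2 × 2 previous-reward × previous-transition table, with a
  logistic regression on ±1 effect-coded factors; separation or empty cells
  yield flagged missing coefficients.

## Synthetic cohorts

`CohortConfig` defaults define the simulated study: 29 subjects × 3
conditions with the 6 condition orders counterbalanced cyclically; one
67-trial two-step session and 150 WM trials (75 per load) per subject ×
condition. Baseline parameters per subject: w ~ Beta(1.3, 2.5)
(right-skewed, mean ≈ 0.34), β ~ lognormal(ln 4, 0.4), α ~ Beta(2, 2),
λ ~ Beta(2, 2), perseveration ~ N(0.1, 0.2) — centred on values typical of
fitted cohorts in this task family. The stimulation effect is an additive
shift of true w (+0.15 under IPS→LPFC by default, 0 under LPFC→IPS),
clipped to [0, 1]; a multiplicative option exists. WM noise is von Mises on
the doubled circle with concentration 4.5 (load 3) and 2.0 (load 6) —
circular SDs of roughly 14° and 24° — scaled by a lognormal subject factor;
stage-2 RTs are base (N(700, 80) ms per subject) plus rare-transition
slowing `50·(1 + w)` ms plus N(0, 150) ms trial noise; 2% of trials are
invalid, independent of condition. Ground truth is stored in a separate
sealed table.

What the generator does **not** emulate: guess/swap contamination in WM
reports, condition-dependent missingness, transition learning, session
practice effects, or any trial-by-trial mechanism of stimulation (the
additive shift on w is an explicit simplification). Passing tests therefore
certify the pipeline's statistical machinery and its sensitivity under
these idealised conditions, not the behaviour of real participants.

## Problem sizes in the test and acceptance runs

Likelihood conservation enumerates all choice sequences of 1–2 trial
sessions for 100 random parameter vectors. Recovery uses 40 agents at 500
trials (and 40 at the study's 67 trials, reported without a threshold).
Signature tests use 50 replicate 150-trial static-environment sessions per
controller with sign tests at p < .01. Calibration uses 2000 null cohorts.
The end-to-end experiment runs 100 replicate simulate→fit→test pipelines
per arm in the test suite (50 per arm in the acceptance script) with 5
optimizer restarts per session and the working-memory stage reduced to a
stub, since the contrast under test uses only the two-step data.

## Known limitations

- The w estimator's shrinkage at 67 trials attenuates condition effects;
  the end-to-end detection rate of a +0.2 true shift with n = 29 reflects
  fitted-scale, not true-scale, effect size.
- Standard errors from the numerical Hessian are unreliable near parameter
  bounds.
- The rank-ANCOVA df convention is one of several in use.
- `bayes_cor_logbf` integrates the sampling density of r, which assumes
  bivariate normal data; heavy-tailed ratios (Δw, Δp) make it a rough
  instrument, as in the analysis it mirrors.
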