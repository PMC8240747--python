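# Methods

## The task and the data model

The package models an effort-based decision-making experiment in which a
participant is offered, on each trial, a reward (1, 3, 6, 9, 12 or 15
virtual apples) in exchange for squeezing a hand-held dynamometer at a
required force (10, 24, 38, 52, 66 or 80% of that participant's own maximum
voluntary contraction, MVC). Each of the 36 reward-by-effort offers is
presented five times — 180 trials in five blocks of 36 — in one fixed
pseudo-random order shared by all participants. On 25% of accepted trials
the participant is exempted from squeezing and receives the reward at no
cost. The analysed observables are the binary choice (accept/reject) and
its latency; force execution itself is not analysed and is simulated as
always successful unless a failure rate is configured. Fatigue and practice
effects are not modelled.

The trial order is one seeded shuffle constrained so that every block
carries a balanced spread of reward levels (with five repetitions and five
blocks, each block is a full factorial). Whether the original task's fixed
order carried block-level constraints is not known; the emitted order is an
arbitrary but fully reproducible stand-in, written out with every simulated
dataset for audit.

## Drift-diffusion model

A trial is a first passage of a Wiener process with drift `V` and noise
scale `c = 1` between absorbing boundaries at 0 (reject) and `a` (accept),
starting at `z·a` (`z = 0.5` is unbiased); the observed RT adds a
non-decision time `t`. The drift rate is a linear function of the offer

    V = v0 + vr·r − ve·e − vre·r·e,

with `r` the reward divided by the design maximum (so `r ∈ (0, 1]`) and
`e` the squared force fraction — a quadratic effort cost, consistent with
motor-control accounts of perceived effort. `ve` and `vre` are stored as
positive cost weights entering negatively. Neither the units of the drift
regressors nor any centring are dictated by the model itself; both choices
are recorded in fit metadata and the unsquared-effort variant is available
behind a flag. Inter-trial variability parameters (sv, st, sz) are
deliberately absent.

### Two threshold conventions

The closed-form summaries

    AR = 1 / (1 + exp(−2·V·a/c²)),     DT = (a/V)·tanh(V·a/c²)

are exact for an unbiased start when `a` denotes the distance from the
starting point to *either* boundary. The subject-level parameter `a` in
`DDMParameters`, however, is the *full* boundary separation (the convention
of hierarchical DDM tooling). `predict_acceptance_rate` and
`predict_mean_decision_time` therefore take the half-separation; the helper
`predict_choice` converts `a/2` internally (and requires `z = 0.5`). The
two conventions are reconciled empirically by the simulator cross-check
below.

### Likelihood

The trial likelihood is the Wiener first-passage density at the chosen
boundary, evaluated by the standard small-time/large-time series with an
automatic regime switch at a truncation error of 1e-7 per evaluation, mixed
with a fixed 5% uniform outlier component supported on RT ∈ [0, 10] s and
split evenly across the two choices. The density integrates to one (tested
to 1e-4) and the accept-side mass equals the analytic boundary-hit
probability. An RT at or below `t` has zero diffusion density; with the
outlier mixture the log likelihood stays finite, and with the mixture
disabled it returns −inf rather than raising.

### Simulator

The brute-force simulator uses Euler–Maruyama steps (`dt = 1e-3` s by
default) with exact Gaussian increments and a Brownian-bridge correction
for within-step boundary crossings, which removes the leading O(√dt) bias
of naive endpoint checking; bridge crossings are assigned the step
midpoint. Paths still unabsorbed at 30 s are restarted and counted. At
z = 0.5 the simulator reproduces the closed-form acceptance rates and mean
decision times within Monte-Carlo error over a grid of drifts and
thresholds (acceptance criterion), and its RT distribution matches the
analytic density with Kolmogorov–Smirnov distance below 0.01 at n = 1e5.

## Synthetic cohorts

Because the clinical data are not public, cohorts are generated with the
statistical structure the analyses assume. Covariates follow the
demographic profile of a late-onset small-vessel-disease cohort: AES
(apathy) mean 32, SD 8; BDI (depression) mean 10, SD 7, with an AES–BDI
correlation of 0.38; age 68 (11); ACE-III cognition 90 (8). Scores are
drawn from a (bivariate) normal and clipped to instrument ranges, with
clips logged. MVC is an arbitrary-unit normal (300, 60) floor-clipped at 1.

Subject parameters are group means plus covariate effects on the
standardized scores plus independent Gaussian noise, truncated into the
supports (a > 0.05, z ∈ [0.02, 0.98], t ≥ 0; truncations logged). Default
group means (a = 2.0, z = 0.5, t = 0.3 s, v0 = 0.3, vr = 1.8, ve = 2.0,
vre = 0.3) were chosen so the default decision space spans near-rejection
to near-certain acceptance (worst cell ≈ 0.15, best ≈ 0.98) with RTs of
roughly 0.5–2 s. Default generating effects — AES lowering v0 and raising
vr, BDI raising a, each by half the between-subject SD of the affected
parameter per SD of the covariate — are calibration values for recovery
experiments giving adequate sign-recovery power at 40 subjects; they are
**not** estimates from any dataset. What passing recovery tests shows is
that the estimation machinery can retrieve effects of this plausible
magnitude from data generated by the model itself; real data add model
misspecification (sequential effects, fatigue, non-Wiener RT tails) that
no synthetic check can rule out.

## Preprocessing

Two exclusion rules, applied in order: RTs strictly below 0.4 s are flagged
as accidental; then, per participant, RTs strictly above that participant's
mean + 3 SD (computed on the trials surviving the first rule) are flagged
as lapses. A bare "3 × SD" threshold without the mean would sit far below
typical RTs, so the mean-anchored reading is used; both the multiplier and
the cut-off are configurable. Rows are flagged with a reason, never
deleted, so re-running the filter on the flagged archive is idempotent.
(Literal idempotence on the kept *subset* is impossible for any
mean + k·SD rule, since truncation contracts the threshold.) Participants
with fewer than two usable trials skip the upper-tail rule, logged.
Force-exempt trials are retained: choice and latency precede the exemption
reveal.

## Hierarchical Bayesian estimation

Subjects are exchangeable draws around group means in an unconstrained
space (log a, logit z, log t, raw drift weights). The exact hyperparameters
of the informative priors used by the reference tooling are published only
in that tool's supplement and are not guessed here; instead the package
ships weakly-informative defaults, versioned in `GroupPrior` so exact sets
can be swapped in: group-mean priors N(log 2, 0.5) for log a, N(0, 0.5)
for logit z, N(log 0.3, 0.5) for log t, N(0, 2) for v0, vr, ve and
N(0, 1) for vre; half-normal group SDs (scale 0.5 for the transformed
structural parameters, 1.0 for drift weights, 0.5 for vre). Draws from
these priors produce acceptance rates spanning (0.05, 0.95) — they are not
degenerate. `a`, `z` and `t` are constant across conditions; `z` is
estimated per subject (it is tested against covariates downstream, so it
cannot be hard-fixed).

The sampler is adaptive Metropolis-within-Gibbs, chosen over gradient
methods to keep the series-based likelihood dependency-light:

1. per subject, a random-walk block update of (log a, logit z, log t) and a
   second block update of the four drift weights, the latter preconditioned
   by the Cholesky factor of the inverse Gram matrix of the per-trial drift
   design [1, r, −e, −r·e] — the drift weights are strongly collinear
   through the offer grid, and isotropic proposals mix across that ridge
   very slowly;
2. conjugate Gibbs updates of each group mean; Metropolis updates of each
   group SD on the log scale;
3. one ancillarity (joint rescaling) move per iteration, cycling over
   parameters: a group SD and all subject deviations around the group mean
   are scaled together. This is the standard interweaving remedy for the
   funnel between a weakly identified subject parameter (here chiefly the
   interaction weight vre) and its group SD.

Proposal scales adapt by Robbins–Monro toward 30% acceptance during
burn-in only, preserving detailed balance afterwards. Initialization takes
prior means with the non-decision time set to half each subject's minimum
RT, with jittered retries (bounded) if the likelihood is non-finite. On a
conjugate toy reduction (normal likelihood substituted for the Wiener
density) the sampler reproduces the closed-form posterior mean and SD
within Monte-Carlo error. The full fit is reproducible from the config
seed; chains run sequentially.

Defaults mirror the reference configuration — 6 chains of 10,000 samples,
1000 burn-in, 5% outlier probability, c = 1 — while tests and recovery
experiments use scaled-down chains (3 × 3000, burn-in 500, 30 subjects)
chosen so the full suite completes on a single CPU; at that scale subject
v0 recovery correlation is ≈ 0.8 and all group-level split-R-hat < 1.1.
The interaction weight vre is only weakly identified at 180 trials per
subject (recovery correlation ≈ 0.2); this is a property of the design
grid, not of the sampler, and mirrors the flat likelihood along r·e.

Convergence reporting uses rank-normalized split-R-hat and bulk effective
sample size (via arviz), flagging parameters above 1.1 (the reference
analysis states no numeric cut-off). For exact copies of a finite chain,
split-R-hat is unity only up to the estimator's small-sample correction.

Posterior predictive checks draw posterior parameter vectors, simulate
replicate datasets of identical schema and size (choices from the exact
boundary-hit probability; RTs by inverse-CDF sampling of the marginal
first-passage density on a 400-point grid), and compare observed per-cell
pooled acceptance rates and RT quantiles (0.1/0.5/0.9) with central 95%
predictive intervals. A fit is checked against the exact dataset it was
estimated on via a content hash. Group-level hypotheses are reported as
posterior probabilities of contrasts over group-mean draws; comparing the
reward and effort weights on commensurate scales multiplies each by the SD
of its regressor over the design grid.

### Fast per-subject estimates

`fit_subjects_map` maximizes the penalized likelihood (Wiener likelihood
plus the fixed group-mean prior) per subject with L-BFGS-B in the
unconstrained space (Nelder–Mead + polish fallback). Replicated recovery
experiments use these point estimates where full posterior inference per
replicate would be wasteful; at 40 subjects × 180 trials the MAP estimates
correlate with truth at ≈ 0.9 for a and v0.

## Choice models

The mixed-effects logistic model has fixed effects of reward, squared
effort and apathy — AES as a continuous z-scored regressor, or the
conventional binary cut-off AES > 34 — with the full reward × effort ×
apathy interaction set and a Gaussian random intercept per participant.
Reward enters as raw apple counts before standardization. The marginal
likelihood integrates the intercept by 15-node Gauss–Hermite quadrature and
is maximized with analytic gradients; standard errors come from the
observed information (central-difference Hessian), per-term F(1, n−k)
statistics are squared Wald t, and BIC = −2·logLik + k·log(n_obs) with k
counting fixed effects plus the intercept SD. With the random-intercept
variance pinned at zero the fit equals pooled logistic regression to 1e-6,
and on common data the fit agrees with lme4's adaptive-quadrature `glmer`
to ~1e-2 (tested through Rscript). Suspected complete separation
(|β| > 15) triggers a flagged ridge-penalized refit, never a silent result.
Random slopes are intentionally absent. The two apathy codings are compared
by BIC on identical observations; comparison across differing observation
sets is refused.

## Association suite

Per-subject summaries (overall acceptance rate; the seven posterior-mean or
MAP parameters) are regressed on clinical covariates: acceptance ~ AES;
acceptance ~ AES + BDI + age + cognition; each DDM parameter ~ AES + BDI +
age, with optional extra severity covariates appended. The robust flavour
of the source analyses is ambiguous ("a weighting function … and clustering
methods"); this package uses OLS point estimates with HC3 sandwich standard
errors — no observation weighting — and offers a cluster-robust variant,
a documented divergence. Per-term F(1, df) is the squared robust t.
Missing questionnaire data are handled complete-case with dropped-row
counts logged. Per-model tests are reported unadjusted, matching the
source presentation; a Bonferroni flag exists for the suite. Pearson
correlations are reported with df = n − 2 and two-sided p.

## Orchestration and reproducibility

A pipeline run is one validated config (unknown keys rejected before any
computation) and one global seed; every stage draws from a named SHA-256
substream, so reruns are byte-identical and each output traces to a
manifest recording config hash, data hashes, package version, seeds and
stage timings. Tables are CSV, reports JSON, figures PNG + SVG. CLI exit
codes separate configuration (2), data (3) and numerical (4) failures.
The recovery experiment repeats simulate → fit → associate over replicate
cohorts and reports sign-recovery rates, slopes, p-values and recovery
correlations per effect; replicate failures are recorded and skipped, not
fatal.

## Known limitations

- vre is weakly identified by the 6 × 6 design; its recovery correlation is
  low and its group SD is the slowest-mixing quantity in the sampler.
- The closed-form DT is the mean over both boundaries; no closed form is
  used for conditional means (the simulator and density cover those).
- The generator draws subject parameters as truncated normals on the
  natural scale while the fit assumes normality in transformed space; the
  mild mismatch is absorbed by the recovery tolerances and mirrors the
  usual situation of fitting data one did not generate.
- Gauss–Hermite quadrature covers a single random intercept only; random
  slopes would need adaptive multidimensional quadrature.
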