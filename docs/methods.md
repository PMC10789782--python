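# Methods

## The task and its two variants

Probabilistic reversal learning (PRL) is a two-option choice task with
probabilistic feedback: choosing the currently "correct" option yields reward
(+1) with probability `p_good` (default 0.8) and punishment (−1) otherwise;
the incorrect option has the reversed contingency. The package simulates the
two variants used across species:

- **Human variant** — 80 self-paced trials over two visual stimuli ("A"/"B");
  the contingencies reverse exactly once, at the fixed midpoint (0-based trial
  40), regardless of performance.
- **Rat variant** — daily sessions of 200 trials over two response locations
  ("left"/"right"); a reversal triggers whenever the subject makes eight
  consecutive correct responses, so the number of completed reversals is
  itself a performance measure.

The consecutive-correct counter counts correct *choices*, not rewarded
trials: under probabilistic feedback a reward-based criterion would make
reversals depend on feedback noise rather than behavior. The counter resets
on an incorrect choice, on each completed reversal, and at session
boundaries (the criterion is not stated to persist overnight; we reset).
Omissions, reaction times and session clocks are not modelled.

## The four candidate models

All models choose by softmax over two options with logits

    logit(a) = tau_reinf * V(a) + tau_stick * 1[a == previous choice]

where `tau_reinf` (reinforcement sensitivity, an inverse temperature) scales
learned values and `tau_stick` (stickiness) is a value-free bonus for
repeating the previous choice — stimulus identity for humans, response
location for rats. Stickiness is a one-trial-back indicator with no decaying
trace, may be negative (anti-perseveration), and contributes nothing on the
first trial. Outcomes are coded ±1 and are the targets of the value updates,
so `tau_reinf` is the single scaling of value differences.

- **M1** (`M1_rp`): Rescorla–Wagner updates
  `V(c) += alpha * (outcome − V(c))` with `alpha = alpha_rew` after reward and
  `alpha_pun` after punishment; no stickiness term.
- **M2** (`M2_rp_stick`): M1 plus stickiness. This is the model class that
  wins the evidence comparison on data of this kind.
- **M3** (`M3_single_stick`): as M2 with one learning rate `alpha_reinf` for
  both valences; M2 reduces to M3 exactly when its two rates are equal.
- **M4** (`M4_ewa`): experience-weighted attraction. An experience weight
  evolves as `n' = rho*n + 1`; the chosen attraction becomes
  `(phi*n*V + outcome)/n'` and the unchosen attraction decays as
  `phi*n*V/n'`. We let both attractions decay, give the payoff only to the
  chosen option, and keep the stickiness term in the choice rule, grouping
  M4 with the stickiness-bearing models; the exact variant used elsewhere in
  the literature varies, so this choice is recorded here as
  ours.

Values start at 0, the experience weight at 1. Within a condition, latent
state is *not* reset at session boundaries: trials are sequenced across all
sessions conducted under one manipulation, and likewise across all 80 human
trials.

Likelihoods are evaluated by a numba kernel (`prlkit._kernels`); an
independent step-wise Python implementation defines the reference semantics
and the suite holds the two to |Δ| < 1e−10.

## Hierarchical model and priors

Parameters are estimated per condition with a hierarchical Bayesian model on
the unconstrained scale: learning rates and EWA decays via inverse-logit,
`tau_reinf` via exp (bound-free and monotone; no upper bound is imposed),
`tau_stick` untransformed. Priors are weakly informative and configurable:
group means ~ Normal(0, 1), between-subject SDs ~ HalfNormal(1), both on the
unconstrained scale.

Between-group designs give each condition its own mean/SD hierarchy.
Cross-over designs share one subject-baseline hierarchy plus per-condition
offsets, reference-coded (the first condition's offset is fixed at zero),
which identifies the baseline/offset decomposition; the condition group mean
is `natural(mu + delta_c)` and contrasts have the same meaning in both
designs: the per-draw difference of natural-scale condition group means (MD).

## Sampling engines

The default engine is an adaptive Metropolis-within-Gibbs sampler written
for this model family:

- each subject's parameter block is updated by random-walk Metropolis with a
  per-subject proposal covariance learned during warmup (Welford accumulator
  reset at 1/4 and 1/2 of warmup so early unconverged history is dropped,
  Cholesky factor refreshed every 25 warmup sweeps with a floored diagonal,
  scaled 2.38/√d with an acceptance-targeting global scale ~0.3);
- group means are updated by their exact conjugate normal conditionals —
  the centered parameterisation is used deliberately so these conditionals
  stay conjugate;
- group SDs are updated twice per sweep: by univariate slice sampling on
  log sigma (stepping-out, Neal 2003) in the centered parameterisation, and
  by an ASIS (ancillarity–sufficiency interweaving) Metropolis move in the
  non-centered parameterisation — holding the standardized subject
  deviations fixed, a log-sigma proposal rescales the whole subject cloud
  about its mean, which is what lets chains escape the hierarchical funnel
  where a collapsed sigma pins every subject to the group mean (weakly
  identified learning rates are prone to this);
- cross-over condition offsets are updated by adaptive random-walk blocks.

A generic adaptive random-walk Metropolis over the same joint log density
(`engine="rwm"`) serves as a dependency-light cross-check; both engines are
deterministic given the seed (per-chain generators spawned from a single
SeedSequence). Defaults are 4 chains × 1000 warmup × 1000 draws; the test
suite and examples use sizes from 2×50 (determinism checks) up to 4×2500
(small-n effect tables), chosen so every fit that makes a convergence claim
reaches split R-hat below the stringent 1.1 gate.

Convergence is monitored by split-chain R-hat (each chain halved before the
between/within variance comparison — stricter than the classic two-part
version, and detects within-chain drift). The stringent gate 1.1 is
enforced for comparisons, with 1.2 as the lenient guideline; model
comparison warns rather than aborts on violations.

## Model comparison

Marginal likelihoods are estimated by iterative optimal bridge sampling: a
moment-matched multivariate normal proposal (no warping) is fitted to half
of the pooled unconstrained posterior draws — split even/odd so both halves
represent every chain segment — and the bridge identity is iterated on the
other half plus an equal number of proposal draws, in log space with
max-subtraction, until the relative change of the evidence estimate falls
below 1e−10 (default; max 1000 iterations, non-convergence raises with
diagnostics). Posterior model probabilities combine the log evidences with
the uniform prior probability 0.25 per model via a stabilised softmax. On
conjugate normal toys with closed-form evidence the estimator is accurate to
a few 1e−3 nats (suite tolerance 0.05 nats in 1-D, 0.1 in 5-D).

## Effect summaries

Condition contrasts are summarised by the posterior mean MD and
highest-density intervals at 75/80/85/90/95%. The HDI is the narrowest
contiguous window of sorted pooled draws containing ⌈level·n⌉ points; ties
between equal-width windows break to the leftmost (deterministic). The
significance flag is the highest level whose HDI excludes zero:
`***` (95%), `**` (90%), `*` (85%), `..` (80%), `.` (75%), `-` (none).

## Behavioral measures

Win-stay and lose-shift condition on the immediately preceding trial's
outcome, use only within-session pairs (overnight gaps break the
one-trial-back dependency), are computed per session and then averaged, and
propagate as missing — never zero — when a subject has no qualifying pairs.
Completed reversals are re-derived from the observed `chose_correct` stream
with semantics identical to the simulator, and checked against it.

Retrodiction draws group-level means and SDs from a fitted posterior,
simulates fresh subjects per condition (default 40 per group — the scale at
which trend-level empirical differences become statistically resolvable) and
contrasts the conventional measures with 95% normal-approximation
Monte-Carlo intervals.

## The synthetic-data generator and what it does (not) show

No raw behavioral data are distributed with the emulated studies, so the
generator is the package's stand-in for them: agents are drawn from
unconstrained-scale normal populations and played through the task
simulators; ground-truth parameters are retained beside every dataset
(hidden from the fitter) to make recovery a first-class experiment. Bundled
presets mirror the emulated designs: 8 vs 8 between-group (neurotoxic
depletion), 11 subjects × 3 conditions cross-over (acute SSRI in rats),
7 vs 7 (repeated and sub-chronic SSRI), 32 vs 33 humans (acute SSRI), a
chronic-human design (sizes unstated in the available text; 32/33 stand in),
and a 40-per-group retrodiction variant. Rats play 5 sessions per condition
(a session count in the range of such multi-day experiments; the exact
number is not critical and is configurable).

The control population — alpha_rew 0.25, alpha_pun 0.45, tau_reinf 3.0,
tau_stick 0.5 on the natural scale, between-subject SD 0.4 unconstrained —
was chosen to be jointly consistent with three qualitative facts about the
emulated studies: (i) performance must sit *below* the noise-chasing optimum
of the 80:20 task, so that lowering the reward learning rate worsens
win-stay and reversal counts (at high learning rates the task's
non-monotonicity reverses that direction); (ii) reward and punishment
learning rates must differ detectably, because the dual-rate model wins the
model comparison in these studies — near-equal rates would make the
single-rate model the correct choice; (iii) stickiness and sensitivity sit
in the ranges typical of fitted rat PRL parameters. Per-condition shifts
follow the reported direction of each manipulation with magnitudes
proportioned to the published natural-scale MDs.

What passing tests show: the pipeline recovers parameters it generated,
selects the generating model, and reproduces the directional behavioral
signatures *under this generative model*. What they do not show: real rats
and humans have sequential dependencies (fatigue, satiety, session drift),
omissions, and individual differences that no parametric population normal
captures; numeric agreement with the published fitted effects is not
expected or claimed, since the raw data behind them are unavailable.

## Numerical choices and degenerate inputs

- Outcome codes are validated to ±1 everywhere; schema errors on CSV input
  name the offending row and column.
- `joint_log_density` includes the log-Jacobian of `sigma = exp(log sigma)`;
  bridge sampling and both engines share the identical density, constants
  included (the reference-coded offset rows contribute no prior constant).
- Proposal covariances and the bridge proposal add escalating diagonal
  jitter before Cholesky factorisation.
- Non-finite density at chain initialisation re-jitters up to 20 times, then
  errors.
- HDI requires ≥ 20 draws; R-hat requires ≥ 2 chains × 4 draws and raises on
  zero total variance.
- Point-mass draw vectors give width-zero HDIs; all-equal evidence gives
  exactly uniform model probabilities; a −inf evidence gives that model
  probability exactly 0.

## Known limitations

- The Gibbs engine's mixing on cross-over designs is slower than on
  between-group designs (the offset/baseline coupling); the defaults handle
  the bundled 11 × 3 design but larger condition counts may need longer
  chains.
- Recovery of learning rates at realistic between-subject spread is
  attenuation-limited: with ~800 trials per subject the per-subject
  likelihood uncertainty is comparable to the population spread, putting the
  truth/estimate correlation ceiling near 0.7–0.85 for `alpha_rew`; single
  runs straddle that range.
- Marginal-likelihood estimates use a normal proposal in the unconstrained
  space; strongly non-Gaussian posteriors (tiny n, extreme parameters) may
  need more draws for stable bridges.
- Effective sample size, rank plots and autocorrelation diagnostics are not
  implemented; R-hat is the only convergence gate.
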