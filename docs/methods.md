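# Methods

## Data model and preprocessing

One row per trial: participant, session (1/2), task (main / control /
orientation), block, trial, aspect ratio (main task only), base 0°
orientation, L1 and L2 responses, response hand. Analyses use only the
response alternatives with equal likelihood at aspect ratio 1: L1 reports
of 0°/90° and L2 reports of 0°/60°/120°; other rows are dropped before
modeling. The binary codings are `r1 = 1` iff L1 was reported at 0° and
`y2 = 1` iff L2 was reported at 0°, with `centered_ar = AR − 1` so that 0
is the maximally ambiguous lattice.

Participants are excluded when a required session is incomplete or when
their main-task diagonal-response rate exceeds 40% in a required session
(an indication of random responding). The threshold is read as a *strict*
inequality — exactly 40% is kept — and is configurable.

Empirical logits for visualization use a Haldane–Anscombe continuity
constant (c = 0.5) applied only to degenerate cells (0 or n successes).
This is an implementation choice: plots of cell logits need a finite value
at the floor/ceiling, and the correction leaves non-degenerate cells
untouched.

## Synthetic observers

The generator reproduces the replica design: 75 participants x 2 sessions,
9 blocks x 70 main trials with 10 trials of each of the seven aspect
ratios (1.3⁻¹ … 1.3) per block in shuffled order, a 90-trial control task
(session 1), and a 240-trial orientation task (4 blocks x orientations
1°–60°, each once per block).

Responses follow the same generative logic the analysis assumes:

* L1: `logit P(0°) = intercept_l1 + proximity · centered_ar`, proximity
  negative (default −8 logits) so closer dot spacing along an orientation
  favors grouping along it; at AR = 1 the two percepts are equiprobable.
* L2: `logit P(0°) = intercept + adaptation · centered_ar + hysteresis ·
  r1` with population defaults 2.3 (hysteresis) and 2.0 (adaptation)
  logits, individual SDs 1.0 and a hysteresis–adaptation correlation of
  0.7 — values inside the ranges estimated for human observers in this
  paradigm.
* Lapses: with probability `lapse_rate` (default 0.1) the response is
  uniform over the non-dominant options (the two diagonals for L1;
  60°/120°/90° for L2). A single mixture parameter keeps recovery
  interpretable; no richer non-dominant response process is modeled.
* Orientation bias: candidate axes {θ, θ+60°, θ+120°} weighted by an
  axial von-Mises kernel `exp(κ · cos 2(candidate − preferred))`.
  Individual κ is lognormal around the population concentration (1.5)
  and can be coupled to the hysteresis latent (`rho_bias_hysteresis`)
  for directed bias–effect tests; preferred directions scatter axially
  around the population direction (default 90°, spread 30°).
* Control task: the first lattice is random, so L1 is simulated with
  proximity 0, and the L2 carryover uses a separate decisional
  coefficient (`control_carryover`, default 0.95 logits) rather than the
  perceptual hysteresis — emulating the reduced first-response carryover
  observed without a percept-inducing first stimulus.

Cross-session structure: each effect correlates with itself across
sessions (`rho_session`, default 0.8, scalar or per effect); hysteresis
and adaptation correlate within a session; remaining cross terms are
filled by the product path and the implied 8 x 8 correlation matrix is
checked for positive semidefiniteness.

What the generator does **not** emulate: sequential dependencies beyond
one trial back, learning or fatigue drifts across blocks, block-level bias
drift, response-time structure, and stimulus-rendering detail (dot jitter
and |a|·|b| invariance are treated as metadata). Passing recovery tests
therefore show that the estimators are faithful when the model family is
correct, not that real data satisfy the model.

Recovery and direction-check cohorts use `lapse_rate = 0`: lapses that
survive the response filter are unmodeled noise that attenuates effects,
and recovery tests are about estimator faithfulness under the assumed
model.

## Hierarchical model and sampler

The Bernoulli logit model is fitted by Hamiltonian Monte Carlo written
in-package, on the unconstrained space:

* non-centered individual deviations `b_i = diag(τ) L u_i`, `u_i ~ N(0, I)`;
* `log τ` for random-effect SDs;
* canonical partial correlations `z = tanh(y)` building the Cholesky
  factor `L` of the random-effect correlation matrix.

Priors (all exposed in `PriorConfig` and recorded in run manifests):
Normal(0, 2) on population effects, half-Normal(0, 1) on SDs, and an
LKJ(η = 1) prior (uniform over correlation matrices), realized as the
equivalent independent scaled-Beta priors on the partial correlations.
These are weakly informative on the logit scale: effects of ±4 logits are
already near-deterministic responses. Prior-predictive success
probabilities have median 0.5 by symmetry (a property test). Sensitivity
to the fixed-effect scale is exercised in the no-pooling test, which pins
the SD prior near zero and recovers the single-level logistic estimates.

Sign-constrained variants (positive-/negative-effects models) sample the
constrained *population* coefficient on a log scale, so the constraint
holds exactly without rejection; individual deviations stay free.

Trials are aggregated into binomial cells per (participant, session,
centered AR, previous percept) — exact for a logistic likelihood — which
makes a gradient evaluation O(number of cells), so desk-scale fits take
seconds. Gradients are analytic except for the few correlation-transform
parameters, which use central finite differences batched into one
vectorized density call; the full gradient is verified against finite
differences in the tests.

Sampling uses jittered-length leapfrog trajectories (up to 32 steps),
dual-averaging step-size adaptation targeting 0.8 acceptance, and a
diagonal mass matrix re-estimated at two warmup checkpoints. Iterations
are per-chain totals with the first half used as warmup by default. The
replication-scale configuration mirrors the study (4 chains x 20,000
iterations, target acceptance .8, maximum tree depth 10); tests and the
acceptance script run 2 chains x 500–2,000 iterations, which the recovery
and direction checks show is sufficient at the problem sizes used. Fits
are flagged unreliable when any split R-hat exceeds 1.01 or bulk ESS
falls below 400; a divergence fraction above 5% is recorded as a warning
with draws still returned. The free-correlation two-session model mixes
slowest and is given longer chains where it is tested.

Two-session joint models exist in three variants for the temporal-
stability comparisons: individual deviations per session independent,
freely correlated (one correlation parameter with a uniform prior), or
fully shared (correlation 1 by construction, with free per-session
population effects and SDs). Within-session correlations between random
terms are omitted in the joint family to isolate the cross-session
question; the session-structured term defaults to the effect under test,
with other terms independent across sessions.

## Bayes factors

* **Bridge sampling**: iterative estimator with a moment-matched
  multivariate-normal proposal on the unconstrained space; half the
  posterior draws fit the proposal, half enter the bridge; iteration to
  relative tolerance 1e-10 (cap 1,000). A simple normal bridge is used
  rather than warp variants — adequate for these posteriors and with
  simpler error theory. The Monte-Carlo error is a relative-MSE estimate
  with an ESS-based autocorrelation correction on the posterior side.
  Accuracy is validated against closed-form evidence on normal–normal,
  Bernoulli–Beta and conjugate-regression toys (within 0.05 log units).
* **Encompassing approach**: BF(constrained vs unconstrained) as the
  ratio of posterior to prior proportions of draws in which *every*
  individual effect has the stated sign; prior draws by forward
  simulation from the model prior (same count as posterior by default).
  Zero posterior counts yield a finite one-sided bound (flagged), never
  ±infinity; zero prior counts raise. The constraint is evaluated on
  individual *total* effects from the unconstrained model, while the
  fitted positive-effects variant constrains the population mean only.
* **Savage–Dickey one-sided tests**: the BF for r > 0 versus r ≤ 0 equals
  the posterior odds of the sign under a symmetric prior, computed by
  draw counting (with finite bounds when all draws agree). Two-stage
  correlation tests (bias–effect relations, cross-session bias stability,
  the two-stage check of the hysteresis–adaptation correlation) use a
  Bayesian correlation model with a uniform prior on r and the reduced
  likelihood of the sample correlation evaluated on a fine grid — fully
  deterministic. The hierarchical model's internal correlation posterior
  is reported alongside, since a two-stage correlation of point estimates
  and the hierarchical correlation answer subtly different questions.
* **Linear vs quadratic bias relations**: bridge-sampled BF between
  conjugate Bayesian regressions with standardized predictors and matched
  normal-inverse-gamma priors (exact posterior draws; the closed-form
  evidence serves as a cross-check in tests).

The sequential design rule monitors the individual-differences and
everyone-shows-the-effect Bayes factors from n = 30 in steps of 5,
stopping when all leave the indecision region (1/6, 6) or at n = 75.

## Circular statistics

Orientations are axial, so all computations double the angles. The bias
vector per participant x session has magnitude
`L = 100 · sqrt((Σ sin 2θ)² + (Σ cos 2θ)²) / n` and direction
`θ̄ = ½ · atan2(Σ sin 2θ, Σ cos 2θ)` mapped into [0°, 180°); `atan2`
replaces a plain arctan ratio so the direction is well defined in every
quadrant. 90° responses (implausible in the hexagonal lattice) are
dropped first; all-90° participants are flagged with an absent bias. Bias
"strength" in all relations is the vector magnitude L. Cross-session
direction stability uses the Jammalamadaka–SenGupta circular–circular
coefficient on doubled angles (cross-checked against an independent
implementation).

## Degenerate inputs and tie-breaks

* Direction of a zero-length orientation vector is reported but
  meaningless; tests guard on L > 0.
* A floating-point wrap at 180° is folded to 0°.
* Equidistant orientation candidates under an extreme bias are chosen
  uniformly among the tied set.
* Correlation analyses with fewer than 3 complete pairs are recorded as
  explicit skip entries (with a warning below 10 pairs); the pipeline
  completes on cohorts as small as two participants.
* Empirical-logit cells with zero trials are omitted rather than
  imputed.

## Problem sizes

The test suite and acceptance script use scaled-down cohorts chosen to
make each check informative at desk scale: recovery on 40 participants x
630 trials (the sufficient statistics per participant are unchanged by
cohort size), direction checks on 16 participants x 630 trials, pipeline
smoke tests on 6 x 105. Cell aggregation makes fit cost independent of
trials per participant, so designs keep the full 630-trial depth wherever
individual-effect precision matters.

## Known limitations

* Static-trajectory HMC mixes more slowly than a dynamic (NUTS-style)
  sampler on funnel-shaped posteriors; the diagnostics flag such fits,
  and the slow-mixing joint-correlated family gets longer chains.
* Bridge sampling with a normal proposal can degrade when posteriors are
  strongly non-Gaussian on the unconstrained scale; Monte-Carlo errors
  are reported and the estimator-consistency test bounds seed-to-seed
  spread.
* The lapse process is not part of the fitted model; with lapsing
  observers, kept-trial lapses attenuate estimated effects (by design the
  preprocessing removes only the directly visible lapses).
* The two-stage correlation tests treat posterior-mean individual effects
  as data; attenuation from estimation noise is taken into account only
  in the hierarchical (internal) correlation posterior.
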