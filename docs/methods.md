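# Methods

This note documents the model, the estimation choices, the synthetic
data generator, and the known limits of what the package's checks can
show.

## Task structure and designs

A session consists of blocks of 80 trials (40 per modality, visual and
tactile interleaved).  Within a block the auditory spatial cue is valid
with a fixed, modality-specific probability.  Three canonical designs
are shipped:

- `exp1` / `exp2`: six blocks drawing per-modality predictabilities
  from {90, 70, 50, 30}%, different between modalities within each
  block (480 trials).  `exp2` additionally pre-cues the target
  modality; the block structure is identical.
- `exp3`: four blocks with complementary levels (90/10 and 70/30, both
  orders), so the cue is equally predictive in both modalities in
  terms of distance from 50% (320 trials).

The exact block-to-level assignment for `exp1`/`exp2` is a
configuration input; the shipped default is a stand-in chosen so that
every level occurs in each modality and both divergence signs occur.
Valid/invalid counts are deterministic quotas (predictability is a
block property, not a sampling rate); cue sides and target elevations
are balanced within block and modality.  Trial timing (cue duration,
SOA, ITI) does not enter any computation and is not modeled.

Block-level factors exported for group analysis are measured in
percentage points: cue predictability as |100·p − 50|, and divergence
as the (signed or absolute) difference between the two modalities'
predictabilities — e.g. 40 for a (90%, 50%) block.

## Preprocessing

Exclusion runs in two stages per subject: (1) misses, incorrect
responses, anticipations (RT < 100 ms, strict); (2) a single-pass 2-SD
criterion on RT around the subject's session mean computed over the
stage-1 survivors (sample SD).  The conditioning set for the SD
criterion is a genuinely open choice; session-wide after stage 1, with
no re-iteration, is the simplest deterministic reading and the one
implemented.  Excluded trials keep their rows: they still update the
ideal observer (the cue–target contingency is observed regardless of
response quality) but never enter any likelihood.  Kept trials get
RS = 1000/RT_ms in 1/s, so plausible RTs of 400–500 ms map to RS of
2–2.5 1/s and the ζ parameters stay on an interpretable scale.

## Estimation

The weighting model has six parameters per fitting unit: w, four ζ's,
and σ.  Since w is the only nonlinear parameter, estimation profiles
it: for each w on a grid (default step 0.01) the ζ's are closed-form
least squares within each validity condition and σ² is the
maximum-likelihood residual variance; the grid optimum is refined by
bounded 1-D search.  A validity condition with fewer than 3 kept
trials (or a degenerate predictor) gets an intercept-only fit — the
10%-predictability blocks leave ~4 trials in one condition and an
unconstrained slope there would be meaningless.  Units with fewer than
6 kept trials return a flagged failure record instead of raising, so
cohort runs survive sparse units.  A likelihood that is flat in w
(zero slopes: w enters only through ζ₂·p_int) is flagged
`w_unidentified` and reported at w = 0.5.

Two fitting granularities exist: per (subject, block, modality), and
concatenated across blocks within (subject, modality) with beliefs
still resetting at block boundaries.  The concatenated unit is the one
used for model comparison and for subject-level weight estimates.

### Model evidence

Three approximations are implemented; `marginal` is the default.

- `marginal`: the bounded model-specific parameters are integrated out
  numerically under uniform priors on [0, 1] — w for the learning
  model, each block's constant level for the alternative — and the
  five shared parameters (two intercepts, two slopes, σ) are
  BIC-penalized.  The uniform prior mirrors the Beta(1, 1) prior the
  observer itself uses.  Because the shared-parameter penalty is
  identical in both models it cancels in every comparison, and each
  bounded parameter pays its exact Occam factor: a block whose level
  is weakly informed contributes almost no penalty, a sharply
  identified one contributes its posterior width.  This matters
  because the two models differ exactly in bounded, block-local
  parameters.
- `bic`: the standard log_lik − (k/2)·ln n.  Its unit-information
  penalty treats each block-constant level as if informed by the whole
  concatenated session and is substantially too harsh for the
  constant model (verified in the model-recovery simulations); kept
  for reference and comparison.
- `laplace`: adds the Hessian-determinant correction at the optimum
  via finite differences, falling back to BIC when the Hessian is not
  positive definite — which is common here because optima frequently
  sit on the w or p boundaries.

### Constant-predictability alternative

The no-learning model replaces the trajectory with one free constant
level per block (ζ's and σ shared across blocks).  It is fitted by
coordinate descent alternating closed-form least squares for the ζ's
with the closed-form per-block optimum of the level; each step lowers
the SSE, so the iteration converges.  The SSE surface is bilinear in
(ζ₂, p) with a reflection symmetry (p → 1−p, ζ₂ → −ζ₂) and can have
local optima, so the descent is multi-started from the empirical valid
fraction and from both orientations of the per-block valid-condition
means.

## Random-effects model selection

Group-level comparison uses the standard variational scheme: each
subject's generative model is drawn from a multinomial with
Dirichlet-distributed frequencies (prior α₀ = 1 per model); posterior
assignments and pseudo-counts are iterated to convergence (tolerance
1e-6).  Exceedance probabilities are computed by seeded Monte Carlo
over the posterior Dirichlet (default 10⁶ draws); for two models the
closed-form Beta integral is available and serves as a cross-check.
The Bayesian omnibus risk is 1/(1 + exp(F_rfx − F_null)) from the
variational free energy of the random-effects model and the exact
evidence of the equal-frequency null, and the protected exceedance
probability is PXP = XP·(1 − BOR) + BOR/K.  Note two properties that
are easy to misread as bugs: with identical evidences the posterior
probability of the null is at least 0.5 (the variational bound can
only raise it), and BOR does not vanish as the per-subject evidence
gap grows — it saturates at a floor set by the number of subjects.

## Synthetic data generator

The generator composes the forward model end to end and defines the
conditions under which all recovery results are stated:

- 21 subjects per cohort, all seeing the same seeded trial sequence
  (a fixed sequence is the standard protocol for sequential-learning
  designs; noise is independent per subject).
- Response parameters ζ₁ = 2.2/2.0 1/s (valid/invalid intercepts,
  mean RT near 450–500 ms), ζ₂ = 0.5 1/s per unit probability, RS
  noise σ = 0.2 1/s (≈ 40 ms at these speeds).
- Generated RS is floored at 0.2 1/s (RT ≤ 5 s): the truncated tail
  is resampled once, then clamped.  This is a generator-only
  convention to avoid absurd RTs from Gaussian tails.
- Behavioral errors are off by default (the response model concerns
  RS only); an optional error rate marks trials incorrect to exercise
  the preprocessing filters.
- The constant generating model draws each block's expectancy
  independently (uniform on [0.1, 0.9]): a subject who does no
  trial-by-trial learning has no access to the realized cue-validity
  stream, so tying the held level to the block's true predictability
  would make the two models asymptotically indistinguishable and
  model recovery vacuous.

What the generator does **not** emulate: sequential RT
autocorrelation, fatigue and practice effects, RT-distribution shape
beyond Gaussian RS noise, misses as a timing process, eye movements.
Passing recovery checks therefore show that the estimation machinery
is correct and well-calibrated under the model's own assumptions, not
that real data satisfy those assumptions.

## Identifiability of w, and a known limitation

The weight is identified through how the *trajectories* of the two
modality-specific estimates differ.  Two structural degeneracies
matter:

1. Within any single block the two trajectories are approximately
   affinely related, and the free per-condition intercepts and slopes
   absorb affine changes — so per-(subject, block, modality) fits at
   realistic noise are close to uninformative about w.  Weight
   estimation should use the concatenated unit.
2. On the complementary design (`exp3`), p_tac ≈ 1 − p_vis holds at
   every trial in *every* block, so p_int(w) ≈ (2w−1)·p_own + (1−w)
   globally: the data pin essentially only the product ζ₂·(2w−1)
   (plus a w ↔ 1−w reflection with sign-flipped slopes).  w is then
   identified only by the small non-affine deviations between the two
   learners' update times.  At the study conditions (σ = 0.2, ζ₂ =
   0.5, 320 trials) subject-level estimates scatter around the truth
   with an SD of roughly 0.25; the median absolute error stays near
   0.1, but the correlation between true and estimated weights is
   bounded near 0.5 regardless of estimator.  On the
   mixed-predictability design (`exp1`), where the two trajectories
   are not globally anti-affine, subject-level recovery reaches
   correlation ≈ 0.85 with median error below 0.1 at the same noise.
   In the noiseless limit w is recovered at grid resolution on every
   design.

The corresponding recovery check on the complementary design is kept
at its stated conditions and its correlation criterion fails there by
construction; the accompanying tests document this rather than
weakening the conditions.

## Numerical conventions

- Estimation grid step 0.01 in w, refinement tolerance 1e-6; the
  marginal evidence integrates the same grid (trapezoid-equivalent
  logsumexp).
- Residual variance floored at 1e-18 so noiseless (σ → 0) fits remain
  finite and comparable.
- The constant-model marginal uses a 401-point grid per block on the
  quadratic per-block SSE.
- BMS Monte Carlo uses 10⁶ Dirichlet draws (XP standard error ≤
  5·10⁻⁴); the variational loop caps at 1000 iterations and flags
  non-convergence.
- All randomness flows through `numpy.random.SeedSequence` spawning:
  one master seed reproduces a cohort bit for bit.
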