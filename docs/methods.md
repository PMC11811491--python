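# Methods

This note documents the models the package implements, the choices made
where the design was genuinely open, the defaults and why, what the
synthetic generator does and does not emulate, and the known limitations.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Observation model: attention-based engagement scoring

One interaction is a cue vector x ∈ [0,1]^M (M = 6 by default: the
smallest size that exercises the attention mechanism non-trivially while
staying in the range of practical annotation schemes). Alignment between a
cue and the target skill goal is the elementwise product e_j = x_j · g_j
with a configurable goal vector g (default all-ones). This is the simplest
kernel consistent with "alignment between the cue and the goal"; the
`EngagementScorer` accepts any goal vector, so alternative alignment
kernels amount to pre-transforming x. Attention is the max-stabilized
softmax of e, and the engagement score E = Σ a_j x_j is then a convex
combination of cue intensities, hence bounded by [min x, max x] — with
cues in [0,1] the score shares the scale of every downstream consumer
(confidence, reward thresholds, score bins). Scores and engagement are
treated as one series: the engagement score is the realized measurement of
the underlying skill score, which is how the closed loop uses it.

The effectiveness table behind the greedy intervention map is the
empirical mean of observed score changes after each intervention within
the score bin of the current score (10 uniform bins on [0,1], shared with
the reward predictor and the policy state key). Unobserved cells default
to 0 and ties break toward the lowest catalog index, so the map is total
and deterministic from the first interaction on.

## Latent state and transition dynamics

The latent state recursion is

  z_i = Γ(x_i, z_{i−1}) ⊙ ( tanh(W₁x_i + b₁) + Σ_{j<i} e^{−ρ(i−j)} A z_j ) + ε

with Γ a logistic-affine gate on the concatenated (cues, previous state)
context and ε isotropic Gaussian noise. Functional forms were open;
tanh/logistic affine maps were chosen because they are bounded,
differentiable and minimal in parameters, and the exponential-decay kernel
makes the "older interactions matter geometrically less" contract literal.
A plain one-step recurrent term is the lag-1 term of the decayed sum and
is not duplicated. z₀ = 0 gives a deterministic cold start. Defaults:
D = 4, ρ = 0.5, σ_ε = 0.05 ("minor fluctuation" relative to the O(1) state
scale); every stochastic call takes an explicit seeded generator.

The one-step transition is

  z_{i+1} = a_i ⊙ ( δ_i · tanh(W₄z_i + b₄) + (1−δ_i) · (W₅x_{i+1} + b₅) ) + ε.

δ_i ∈ (0,1) is a logistic novelty gate, δ_i = logistic(c₀ − c₁‖x_{i+1} −
x̄_i‖₂) with x̄_i the running cue mean of the session: persistence is high
exactly when the new interaction carries little new information (defaults
c₀ = 0, c₁ = 1, centering δ near 0.4–0.5 for unit-scale cues). The
recurrent map is tanh-squashed because the convex combination only keeps
trajectories bounded if one branch is bounded; the cue map stays affine so
novel cues can move the state freely. Attention lives in the
D-dimensional state space (the only shape-consistent reading of an
elementwise product with a length-D state); because a softmax vector
shrinks magnitudes (every component < 1), a config flag
`attention_renorm: none|max|sum_to_D` optionally rescales it for long
runs. The verbatim form (`none`) is the default; the renormalized forms
also provide the exact-degeneracy hooks the compositional tests use.

### Fitting

`fit_transition` estimates (W₄, b₄, W₅, b₅) by teacher-forced least
squares: the one-step MSE of predicted next states, plus λ_Ω times a
smoothness penalty on the predictions (default λ_Ω = 0 — the penalty is a
stabilizer for rough observational data, and biases parameter recovery
when the truth is the model itself). Attention and novelty-gate parameters
are fixed hyperparameters during the fit. The optimizer is full-batch
gradient descent with analytic gradients and Armijo backtracking (halving
step, growth factor 2 on acceptance, max 5000 iterations, relative-change
tolerance 1e−8): dependency-light, deterministic, and non-increasing in
the objective by construction. Degenerate data (all transitions identical)
fits without error and is flagged.

A note on identifiability: with a *constant* blend weight δ the intercept
of the tanh branch and the intercept of the affine branch are nearly
collinear (tanh is locally linear), and only the curvature separates them.
The varying novelty gate breaks this collinearity, which is why the
parameter-recovery study keeps it at its defaults. The recovery study
draws ground-truth entries with magnitudes in [0.3, 0.8] so that relative
error is well defined for every entry.

## Reward stack

Config keys are role-prefixed because the method reuses symbols across
unrelated roles. Symbol map: `sensitivity_alpha` (α, immediate-reward
sensitivity), `scale_gamma` / `discount_beta` (γ, β of the cumulative
reward), `penalty_lambda` / `improvement_threshold_delta` (λ, δ of the
penalty), distinct from the TD `learn_rate_beta` / `discount_gamma`, the
smoothing `smooth_lambda`, and the fit's `reg_lambda`.

Defaults: α = 1 (improvement counts as much as level), γ = 1, β = 0.9,
λ = 0.1 with threshold 0 (a mild flat penalty for interventions that fail
to improve engagement at all; the indicator is strict, so exactly-at-
threshold incurs no penalty). At β = 0 the newest reward survives
(0⁰ ≔ 1), the only reading under which "emphasize recent interactions"
holds in the limit. The predictive reward's conditional mean is the binned
empirical next-score mean with a martingale prior (cold cell → current
score): deterministic and model-free. The per-session final objective sums
the discounted cumulative reward over every prefix; this double-discounts
early rewards relative to a standard RL return, so it is reported as a
session diagnostic while the policy optimizes the TD target (equivalently
the standard discounted return).

## Policy

The Q-table is keyed by the score bin (10 uniform bins on [0,1], last bin
closed at 1.0, out-of-range scores clipped with a warning); a sign-pattern
code of the latent state can be appended behind a flag, at the cost of up
to 2^D times more cells. Defaults: learn rate β = 0.1, discount γ = 0.9,
cold-start Q = 0. ε-greedy includes the greedy arm in its uniform draw, so
the greedy arm's selection probability is (1−ε) + ε/|I| — the calibration
tests use this formula. Exploration decays across training sessions as
ε_t = max(0.05, 0.3 · 0.999^t). Mini-batch updates apply the single-step
update sequentially in batch order, which makes them exactly the fold of
the one-step rule and therefore reproducible.

The closed loop per step: observe cues → engagement score → confidence
over the rolling window → Bernoulli(p(c)) decides whether to intervene →
ε-greedy arm at the smoothed intensity → next observation → penalty-
modified immediate reward → TD update (intervened steps only) and
intensity adaptation. TD transitions use the realized next state key even
when the next step is un-intervened.

`q_learn_mdp` runs the same TD kernels on a finite MDP with known
transition/reward tables (the engagement dynamics discretized over score
bins by integrating the Gaussian step kernel across bin edges, boundary
mass absorbed into the edge bins). Episodes restart from a uniform random
state every 5 steps: the mean-reverting dynamics concentrate visits in a
few bins, and without exploring starts the rarely visited bins' values do
not converge within a practical step budget.

## Confidence-based adjustment

Confidence c = exp(−Var(window)) over the last K = 5 engagement scores
(sessions shorter than K use all available scores with K replaced by the
count). The intervention probability is the linear map p = p_min +
(p_max − p_min)(1 − c), defaults [0.2, 0.9]: stable engagement reduces
prompting, unstable engagement increases it. The direction was specified;
the linear form is the simplest monotone map onto a configurable range.
Intensity φ(j) moves by η · c · ΔE (η = 0.1) and is exponentially smoothed
(λ = 0.8); the smoothed value, capped to [0, 2], multiplies the
intervention's ground-truth effect in the simulator — giving intensity an
operational meaning in the closed loop, which the method otherwise leaves
abstract.

## Synthetic cohort generator

Ground truth per child: latent engagement ℓ_{t+1} = c·ℓ_t + (1−c)·b +
effect(j_t)·intensity + N(0, σ²), with baseline b ~ U(0.3, 0.7), carryover
c ~ U(0.5, 0.9), σ = 0.05, one designated intervention at +0.3 and the
rest at 0 by default. Observed engagement is ℓ clipped to [0,1]; cues are
per-cue loadings (U(0.5, 1)) times ℓ plus N(0, 0.05²) noise, clipped.
The generator is deliberately simpler than the latent-state model the
package fits — a mean-reverting AR(1) — so that recovery and policy tests
have closed-form references (e.g. the steady-state engagement shift of a
policy intervening with probability p is effect·p/(1−carryover)). Child
seeds are spawned from the master seed via numpy `SeedSequence` spawn
keys, making cohorts bit-reproducible and children independent.

Clipping censors the AR(1): tests that check closed-form AR(1) quantities
(steady-state shift, effect-size regression) use interior configurations
(smaller effects and carryover, mid-range baselines) where clip events do
not occur; the policy tests use the defaults, where saturation at 1.0 is
realistic and harmless to the ranking of interventions. The generator
emulates engagement dynamics with additive intervention effects and noisy
linear cue read-outs; it does not attempt to mimic real ASD behavioral
statistics, session non-stationarity, missing data, or annotator
disagreement — passing tests demonstrate correctness of the machinery on
a known truth, not clinical validity.

## Problem sizes and numerical choices

The study sizes used by the tests and the acceptance script: kernel
oracle batteries at 1000 random inputs (agreement to 1e−12); TD vs value
iteration on 10 bins × 3 interventions over 2×10⁵ steps (sup-norm
tolerance 0.05); ε-greedy calibration at 10⁵ draws (±0.005); parameter
recovery on 200 sessions × 50 steps at D = M = 2, σ = 0.02 (10% relative
error); policy improvement with 500 training sessions of 30 interactions
and 100 paired evaluation replicates (4σ Monte-Carlo band); null
calibration with all effects zero at the same sizes. These sizes were
chosen so each property is measured well inside its tolerance while the
whole suite runs in well under a minute on one CPU.

Floats serialize with Python's shortest-round-trip repr (bit-exact on
reload); manifests contain no timestamps, so every CLI command is
byte-reproducible from (config, seed). Logistic outputs are mathematically
in (0,1) but round to exactly 0.0/1.0 in double precision once |logit|
exceeds ≈36; boundedness tests probe the representable regime.

## Known limitations

* Tabular Q-learning pools heterogeneous children into shared score bins;
  rarely visited extreme bins can retain an incorrect greedy arm on some
  training seeds even when the frequently visited bins are correct, which
  lowers the best-arm share of a greedy rollout. Latent-state sign codes
  (the optional key extension) trade sample efficiency for context.
* The transition fit estimates the state/input maps with attention and
  novelty-gate parameters held fixed; joint estimation of all blocks is
  out of scope and would need stronger identification.
* The gradient-descent fitter is full-batch and single-start; the
  objective is non-convex, and pathological initializations could find
  local minima (zero initialization has been well behaved on the scales
  tested).
* The observational `fit` CLI derives latent trajectories from cues with a
  fixed seeded encoder before fitting transitions; the fitted dynamics are
  therefore dynamics of that encoding, not of an inferred latent posterior
  (no latent-variable inference is attempted).
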