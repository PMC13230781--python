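# Methods

## Task model

The environment is a repeated two-player Chicken game against programmed
opponents. Each trial both players choose *Swerve* (coded 1) or *Go
straight* (coded 0) and receive the payoff-matrix entry for the joint
action. Opponents act by a fixed Bernoulli policy — the high-competitive
opponent (HCO) goes straight with probability 0.70, the low-competitive
opponent (LCO) with 0.30 — independently across trials, so the only
structure a learner can exploit is each opponent's stationary tendency.

Two designs are implemented:

* **study1** (preschool variant): simplified matrix in "flowers"
  with GS > SS = SG > GG. The printed sources give the ordering, the
  "three flowers" unilateral-defection payoff, a zero mutual-defection
  payoff, and the closed-form value difference `EV = 1 − 3p`; the entries
  (gs, ss, sg, gg) = (3, 1, 1, 0) are the reconstruction consistent with
  all four constraints and are exposed as an overridable preset. Each
  opponent appears in four contiguous blocks of 10 trials (80 total);
  opponent order alternates across subjects (counterbalanced).
* **study2** (school-age variant): full matrix with losses,
  GS > SS > SG > GG and a crash cost of 30. Only the mutual-defection
  entry (−30) is pinned by the sources; the default preset
  (30, 10, −10, −30) respects the ordering and symmetry and is fully
  configurable — all belief-family formulas are derived from the
  configured matrix, never hard-coded. 50 trials per opponent are
  interleaved in uniformly random order (100 total); "blocks" are
  analysis bins of 20 consecutive trials.

No-response trials exist only in real data; the CSV reader drops rows with
a missing choice and counts them. Reaction times, cover-story elements and
questionnaires are out of scope.

## Model bank

Twelve models share one interface (state, expected value, choice rule,
update rule). Per-opponent state is strictly separate: trials against one
opponent never move the other's state.

* **M0** — a delta-rule learner with learning rate fixed at zero and
  zero-initialised values: choice probability is exactly 0.5 every trial.
  Its inverse temperature β is retained for fidelity with the bank's
  shared structure but is unidentifiable (the likelihood is flat in β).
* **M1 (reward-based)** — Rescorla–Wagner updating of the *chosen*
  action's value toward the received reward, `V ← V + α(R − V)`. The
  unchosen action is frozen: only the chosen action yields a reward, so
  this is the standard delta-rule convention; the choice is isolated in
  one function should both-action updating ever be wanted. Initial values
  are zero for both actions (configurable), which makes M0 a coin-flip
  baseline.
* **M2 (belief-based / fictitious play)** — tracks the opponent's swerve
  probability `p ← p + α(O − p)` from the observed opponent action O,
  starting at p = 0.5, and derives action values from the payoff matrix:
  `V_S = p·SS + (1−p)·SG`, `V_G = p·GS + (1−p)·GG`, so
  `EV = A + B·p` with `A = SG − GG`, `B = (SS − SG) − (GS − GG)`.
* **M3 (second-order belief)** — augments the belief update with an
  influence term: `p ← p + α(O − p) + κ(Q − q)` where Q is the
  participant's own action and q the opponent's inferred probability that
  the participant swerves. q inverts the participant's own softmax,
  `q = (logit(p)/β − A)/B`, which under the study1 matrix reduces exactly
  to `q = 1/3 + log((1−p)/p)/(3β)`. The generic inversion is used for any
  matrix. Beliefs are clipped to [1e−6, 1 − 1e−6] before the logit and
  after every second-order update to keep the likelihood finite.
* **M4 (preference-only ablation)** — no updating; the expected value is
  frozen at its initial state (0 for the reward variant M4-1; `A + B/2`
  for the belief variant M4-2) so the choice probability is the constant
  `σ(β·EV₀ + θ)`. β and θ trade off against each other in M4-2
  (identifiability caveat); the model exists as an ablation baseline, not
  for interpretation of its parameters.

Within M1–M3 the sub-models are: one learning rate (`-1`); separate rates
α_h (HCO trials) and α_l (LCO trials) (`-2`); separate rates plus a
swerve-preference bias θ added inside the softmax (`-3`). M3 sub-models
additionally carry κ.

Parameter supports: α, α_h, α_l, κ ∈ [0, 1]; β ∈ [0, 10]; θ unbounded.

**Reward scaling.** Study-2 payoffs are an order of magnitude larger than
study-1 flowers. To keep β on a comparable scale, rewards are divided by
the design's `reward_scale` (study1: 1; study2: 10) before entering the
delta rule. The belief family uses matrix units consistently in its value
and second-order formulas and is not rescaled.

## Hierarchical inference

Subject-level parameters are modelled on an unbounded scale:
`phi_i = mu + sigma * z_i`, `z_i ~ N(0, 1)` (non-centred), with hyperpriors
`mu ~ N(0, 1)` and `sigma ~ half-Cauchy(0, 3)` (scales configurable per
parameter). Bounded parameters are mapped into their support by the
standard-normal CDF, `phi = lo + (hi − lo)·Φ(raw)`; θ passes through
unchanged and is modelled hierarchically like every other parameter (a
flat, non-hierarchical θ can be emulated by fixing its prior scales).

The posterior is sampled by **slice sampling within Gibbs**: one sweep
updates each hyper mean, each log hyper sd (with the log-scale Jacobian)
and each latent z coordinate by univariate slice sampling (step-out width
2.0, capped step-outs and shrinkage). The whole sweep, including the
trial-by-trial likelihood, is numba-compiled, which makes the
study-matched default (4 chains × 3000 warmup × 1000 retained draws =
4000 samples) practical on one CPU for cohorts of tens of subjects. Slice
sampling was chosen because it is tuning-free and robust for these smooth,
moderate-dimensional posteriors; it requires no gradients, so the same
sampler serves every model in the bank.

Convergence uses the classic split-R̂ (each chain halved; pass iff
max R̂ < 1.1 across hyper- and subject-level parameters), cross-checked in
tests against arviz's split implementation. Chains are initialised mildly
overdispersed (hyper means from N(0,1)); identical seeds give identical
draws. Reduced presets are provided: `ci` (2 × 500/500) and `recovery`
(2 × 300/300) for desk-scale work; the reported problem sizes in the test
suite use these.

## Model comparison

Pointwise log-likelihoods (one observation = one trial; subject-level LOO
is a trivial re-grouping of the stored array) feed PSIS-LOO via arviz's
Pareto-smoothed importance weights, with the sampler's relative efficiency
estimated from hyper-parameter effective sample sizes. Observations whose
likelihood is constant across draws (probability pinned near 1) carry
constant importance ratios; they are scored exactly by the unsmoothed
average and their undefined Pareto k is reported as −inf rather than
flagged. Genuine Pareto-fit failures fall back to unsmoothed weights with
k = +inf and are counted in `n_bad_k` (threshold 0.7).

Stacking weights maximise the pooled log of the weighted leave-one-out
predictive density over the simplex (softmax parameterisation, BFGS with
analytic gradient); ties keep the uniform initialisation. Family-level
support is the pooled log predictive density of each family's internally
stacked mixture — the exact family-aggregation arithmetic is not printed
in the sources, so this interpretation is the package's own, documented
choice; pooled weights across all fitted models are reported alongside for
transparency. Pairwise elpd differences carry standard errors and a
"non-decisive" label when |Δelpd| < 2·SE.

## Validation procedures

* **Posterior predictive checks** simulate each subject against the
  *recorded* opponent-choice sequence (conditioning on opponent behaviour
  isolates the participant model; a re-sampling mode is available through
  `simulate_session`), using one posterior draw per subject per replicate
  ("draws" mode, default) or posterior means ("point" mode). "Trial
  level" is operationalised as the mean swerve rate across subjects at
  each within-opponent trial position; Pearson correlations between
  observed and simulated series are reported per opponent, with missing
  values and a cause when a series has zero variance.
* **Model recovery** simulates cohorts from each bank member at its
  study-derived group condition, refits the candidate bank, and tallies
  LOOIC winners into a confusion matrix (rows sum to 1; failed fits are
  logged and excluded). Default 10 datasets per generating model.
* **Parameter recovery** draws group-level ground truths uniformly from
  each parameter's support (θ from [−1, 1], matching the bulk of its
  N(0, 1) prior), simulates a cohort with raw-scale between-subject sd
  0.25, refits, and correlates recovered group posterior means with the
  truths across iterations (default 30, per the study's procedure).

## Generating conditions

Synthetic cohorts default to the winning-model group posteriors of the
corresponding study populations: study1 reward learner
(α_h = 0.32, α_l = 0.20, β = 0.37, θ = 0.09), study2 young reward learner
(α_h = 0.05, α_l = 0.09, β = 0.80, θ = −0.57) and study2 belief learner
(α_h = 0.015, α_l = 0.009, θ = 0.06). The study2 belief-family inverse
temperature is not available in the printed tables; β = 1.5 is used as a
plausible reduced-exploration value for the older groups. Between-subject
heterogeneity defaults to sd 0.25 on the raw scale (moderate spread without
saturating the probit map). Model/study pairs without a study-derived
condition fall back to mid-range values (α ≈ 0.25, β = 1.0, κ = 0.2,
θ = 0).

## What the synthetic data do and do not show

The generator emulates the designs' trial arithmetic, opponent policies,
payoffs and counterbalancing, with participants drawn from the same
hierarchical population the fitter assumes — so recovery and selection
tests demonstrate *internal* consistency: the estimator identifies its own
generative process at study-like sizes. Real children differ in ways the
generator does not model: non-stationary strategies, lapses and timeouts,
block-order effects, and any mismatch between the true learning process
and the bank. Passing tests therefore validate the machinery, not the
developmental claims; analysing the real OSF data would require only the
CSV reader plus a column-mapping config.

## Problem sizes and numerical choices

The test suite runs reduced but study-plausible scales chosen as package
defaults: parameter recovery at 40 subjects × 80 trials × 10 iterations;
model recovery over {M0, M1-3, M2-3} with 5 datasets × 30 subjects;
family selection with 5 replicate cohorts of 30 subjects against a
four-model sub-bank (both families represented by their 1- and 3-variants).
Full-scale modes (30 iterations, 10 datasets, the complete bank, the
4 × 3000/1000 sampler) are plain arguments away and use the same code
paths.

Numerical details worth knowing: logistic log-probabilities use the
log1p-based stable forms; belief clipping bounds are 1e−6; slice sampling
caps step-outs (20) and shrinkage steps (100, then retains the current
value — never observed in practice); β enters the second-order inversion
guarded by max(β, 1e−6); degenerate payoff matrices with B = 0 are
rejected. The seed of every stochastic entry point fully determines its
output; MCMC results are bit-reproducible per platform for a fixed seed
and configuration.

## Known limitations

* M0's β and M4's β/θ are partly or wholly unidentifiable by
  construction; they are baselines, not interpretable fits.
* Trial-level PSIS-LOO on hierarchical fits yields elevated Pareto k for
  influential observations at small draw counts; comparisons carry SEs
  and a decisiveness label for exactly this reason.
* The slice-within-Gibbs sampler updates one coordinate at a time; for
  strongly correlated posteriors (e.g. β with θ in M4-2) mixing is slower
  than a gradient-based sampler would be. The split-R̂ gate guards this.
* The study2 payoff entries other than the crash cost, and the study2
  belief-family temperature, are reconstructions/choices as noted above.
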