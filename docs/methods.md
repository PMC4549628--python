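# Methods

This note documents the models, the numerical choices behind them, the
synthetic-subject generator, and the known limits of what the test suite
demonstrates.

## Task model

Each block of 42 trials is an independent learning episode: the tried-action
sets and the dynamically assigned correct responses are cleared at block
boundaries, working memory is emptied, and (by default) cached value states
are reset too (`run_session(..., reset_values=False)` keeps values across
blocks).  The stimulus sequence is balanced within each block (14
presentations per stimulus) and shuffled by a seeded generator; no constraint
is placed on immediate repeats.  Only *distinct* incorrect responses advance
the required-error count, which preserves the guarantee that a non-repeating
learner makes exactly 1/3/4 errors for S1/S3/S4.  The response deadline and
the feedback delay of the original experimental procedure are not modeled;
neither enters any model equation.

## Habitual system

Tabular Q-Learning with learning rate α ∈ (0,1), inverse temperature
β ∈ (0,100) and discount γ.  The default is γ = 0: stimuli are independent
and reward immediate, so the bootstrap term carries no information in this
task.  γ remains a configurable field for other environments.  Q-values are
initialized at 0.  The softmax is computed with max-subtraction; it is
invariant to adding a constant to all values, a property the
entropy-coordination model relies on (an ignorant Q-Learner adds a uniform
offset that does not perturb the combined policy).

### Kalman Q-values, VPI, reward rate

The selection model needs Gaussian beliefs N(μ(s,a), σ²(s,a)).  A scalar
Kalman filter is kept per (stimulus, action): gain K = σ²/(σ²+R), mean
updated by K·(target − mean), variance shrunk by (1−K) plus process noise
(default 0; the task is stationary).  Full Kalman Temporal Differences with
cross-covariances is out of scope.  Variances are initialized at η, the
family's "covariance initialization" parameter (range 1e-5 – 1e-3).

The observation noise R is a free design choice nothing in the family's
parameter set fixes.  It defaults to η itself: with prior variance equal to
observation noise the gain sequence is 1/2, 1/3, 1/4, …, i.e. the posterior
mean is the running sample mean of observed targets, and after convergence
the means sit where a plain Q-Learner's values would.  An O(1) observation
noise against an η-sized prior would give gains of order η and the habitual
means would never learn — the selection model then stays at chance after its
working-memory phase ends, which contradicts the architecture's intent.

VPI(s,a) is the expected improvement from knowing a's value exactly: with a₁
the best and a₂ the second-best action by posterior mean (ties broken by
lowest index),

    a = a₁:  (μ₂−μ₁) Φ((μ₂−μ₁)/σ₁) + σ₁ φ((μ₂−μ₁)/σ₁)
    a ≠ a₁:  (μ_a−μ₁) Φ((μ_a−μ₁)/σ_a) + σ_a φ((μ_a−μ₁)/σ_a)

equivalently E[(μ₂−X₁)⁺] and E[(X_a−μ₁)⁺] under the Gaussian beliefs (the
Monte-Carlo oracle used in the tests).  VPI is nonnegative everywhere and 0
in the zero-variance limit.  The per-stimulus reward rate is an exponential
moving average R̄(s) ← (1−σ_r)R̄(s) + σ_r·r, initialized at 0.

## Bayesian Working Memory

A fresh item encodes the last trial deterministically; rows for contexts not
observed on that trial are uninformative (uniform over actions, 0.5 for the
outcome).  These entries matter once decay has leaked stimulus mass: decay
blends every pmf toward uniform (outcome entries toward 0.5) at rate ε once
per trial, applied to the pre-existing items after the new item is pushed —
an item is never decayed on its own trial.  k decays equal the closed-form
mixture (1−ε)^k·fresh + (1−(1−ε)^k)·uniform, which is what the compiled
replay kernels use.

Retrieval folds items most-recent-first into a joint over (s,a,r).  The
joint is initialized uniform with mass 1/(|S||A||R|) per cell so that
processing zero items yields the uniform policy; the unnormalized
accumulation is harmless because the per-outcome normalization follows.
Action values are Q(a) = p(a|r=1,s_t)/p(a|r=0,s_t) with the denominator
floored at 1e-8 (with the uniform initialization it is positive anyway), and
the policy is the normalized Q — no second temperature parameter.

Stopping: retrieval continues while H > θ and unprocessed items remain, i.e.
equality counts as reaching the threshold.  The distinction matters only at
the exact maximal entropy (a θ at log₂|A| stops retrieval immediately);
below it, ties have measure zero.

A consequence of the uniform initialization worth knowing: a single positive
recall yields p(correct) ≈ 0.886, not 1.  The BWM-only agent therefore
plateaus near 80–90% accuracy — the same plateau the architecture is known
for — and a dual-system agent surpasses it only because the habitual values
sharpen the summed policy.

## Coordination models

*Entropy-based coordination.*  H^QL (between-trial learning progress) and
H^BWM (within-trial retrieval progress) jointly drive the decide/retrieve
choice through the logistic p(deciding) given in the README.  It is exactly
1 when i = n (in particular on a session's first trial) and is monotone in
i, n, and both entropy deficits.  At decision, Q_final = p^BWM + Q^QL — the
*normalized* BWM policy, not the raw ratios (the ratios' scale is unbounded
and would swamp β_final; a flag selects the raw variant).  The default
fitting configuration ties β_final to β, giving the family seven free
parameters.  The policy is stochastic through the sampled retrieval depth,
so likelihood evaluation averages per-trial probabilities over n_rep = 3
seeded replays.

*Weight-based mixture.*  The BWM always runs (its i feeds the sRT); the
weight is a per-stimulus posterior updated from each system's outcome
likelihood p(r|s,a) = p(a|s) if r=1 else 1−p(a|s).  w = 0 and w = 1 are
absorbing, and w stays in [0,1] for any evidence sequence.  When both
likelihoods are 0 the weight is left unchanged.

*VPI-based selection.*  Implemented per action: actions with VPI > R̄ take
their value from the BWM policy, the rest from the Kalman means; ties go to
the habitual branch; if no action exceeds R̄, retrieval is skipped entirely
(i = 0, a fast decision).  A whole-trial mode (all-BWM when any action
qualifies) is available via `per_action=False`.

*Lesion analysis.*  `lesion_entropies` replays an agent under teacher
forcing and reports the final-policy entropy with both contributions, with
the QL contribution removed, and with the BWM contribution removed, each per
that agent's own combination rule.

## Reaction times and representative steps

sRT = (log₂(i+1))^σ + H.  σ is read as an exponent on the log term (a
multiplicative reading is selectable by flag).  A habitual decision (i = 0)
has sRT = H exactly, so a pure Q-Learner's sRT only decreases as its values
converge.

Model sRTs (arbitrary units) and subject RTs (seconds) are standardized per
individual by median and interquartile range before comparison.  Trials map
onto 15 representative steps: per stimulus and block, presentation p maps to
acquisition step p while p ≤ required_errors+1; consolidation steps start
after the first correct outcome at presentation c, with presentation
c+offset+j mapping to step 5+j.  The offset defaults to 1 (step 6 is the
*second* post-correct presentation); values 0–2 are accepted because the
phrasing of the original reordering is ambiguous, and the flag records
rather than resolves that ambiguity.  Missing steps are reported absent,
never imputed.

## Fitting pipeline

Teacher forcing: the candidate's policy is evaluated at each trial, the
probability of the recorded action is logged, and the candidate is updated
with the recorded (s, a, r).  Likelihoods are handled in log space with
per-trial probabilities floored at 1e-12 (a warning is emitted).  Candidates
whose sRT distribution is degenerate (zero IQR) get a flat standardized
series instead of an error, which the RT objective scores poorly — the
optimizer needs no special casing.

NSGA-II is implemented in-package (fast non-dominated sort via a vectorized
dominance matrix, crowding distance, binary tournament, SBX crossover
η_c=15, polynomial mutation η_m=20, p_m=1/d), maximizing (log L̂, E_RT,
diversity).  Diversity is the mean Euclidean distance to the k = 5 nearest
neighbours in normalized gene space, recomputed for each population it
ranks; it is dropped when the final front is extracted.  Genes live in
[0,1]^d; λ₁, λ₂ and η are decoded on a log₁₀ scale because their ranges span
several decades; the capacity N decodes to an integer in 2–9.  Runs are
deterministic given the seed.

Aggregation normalizes each objective to [0,1] by the front's own ideal and
nadir.  Augmented Chebyshev minimizes max_i λᵢ(1−xᵢ) + ε Σᵢ λᵢ(1−xᵢ) with
weights (0.5, 0.5) and ε = 0.001 (both unconstrained by the source analyses;
ε > 0 keeps the winner Pareto-optimal).  OWA sorts coordinates ascending
before weighting; distance aggregation measures Euclidean distance to the
unit reference point.  Ties break by better choice fit, then model-id order.
BIC = −2 log L̂ + k ln n uses each family's free-parameter count (2 for QL,
4 for BWM, 7 for the dual systems).  Choice-only optimization keeps the
diversity objective alongside the likelihood.

The teacher-forced replays are compiled with numba (`dualsys.kernels`); the
kernels mirror the reference agents and the test suite asserts exact
agreement for the deterministic families and statistical agreement for the
stochastic one, so the fast path cannot silently diverge from the reference
implementation.

## Synthetic subjects

A ground truth (family, parameters, RT-noise SD, seed) is played closed-loop
through the task; the recorded RT is the trial's sRT plus Gaussian noise
(default SD 0.25 in sRT units, truncated at zero).  The generator's purpose
is to emulate the cohort structure of the behavioral study this package
models — 4 blocks × 42 trials, near-stereotyped acquisition, group-mean RTs
that rise during acquisition and fall during consolidation.  Ground-truth
parameters are therefore drawn from the *competent* sub-ranges in
`synth.DRAW_RANGES` (e.g. σ in 0.5–3, β in 8–15, λ₁ log-uniform in 5–100)
rather than from the full fitting bounds: most of the admissible parameter
space describes agents that never learn, and no human learner in such a
study resembles them.  Draws across the full bounds also produce sRT
exponents whose standardized RT scales (10⁶ and beyond) are dominated by a
handful of trials, which no empirical RT distribution does.

What the generator does not emulate: individual differences in RT
distribution shape beyond the group pattern, sequential effects, lapses, or
any within-subject nonstationarity besides learning itself.  Passing tests
on synthetic cohorts therefore demonstrate pipeline correctness and
qualitative signature reproduction, not quantitative fit to any particular
human dataset.

## Problem sizes used by the test suite

The end-to-end recovery analysis uses 20 synthetic subjects (4 per family)
with NSGA-II populations of 40 over 100 generations per model and subject,
and n_rep = 3 replays for the stochastic family; the RT-signature analyses
use 54-session groups; oracle equivalences use up to 500 random points
(Pareto filter), 3-item stores at 1e-12 tolerance (working-memory joint),
and 10⁶ Monte-Carlo draws within 3 standard errors (VPI).

## Known limitations

* **Parameter identifiability.**  With 168 trials of near-stereotyped
  behavior, decision parameters are weakly identified: near-greedy
  generators leave an α–β likelihood ridge, and the retrieval gains λ are
  only loosely constrained.  In the package's own recovery analysis the
  *model* is recovered reliably (dual-system generators are selected as
  dual-system >90% of the time) and the sRT exponent recovers well (rank
  correlation ≈ 0.8), but the pooled rank correlation over all continuous
  parameters is ≈ 0.56 — the optimizer is converged (its best likelihood
  matches or beats the generating parameters'), so this is a property of the
  data, not of the fit.
* The BWM's uniform joint initialization caps single-recall confidence at
  ≈ 0.886; consequently the faithful weight-based mixture cannot exceed
  ≈ 0.9 accuracy until its weight has shifted to a converged habitual
  system.
* sRT is a two-term abstraction; no drift-diffusion or race-model dynamics,
  and no within-trial time units.
* The scalar Kalman filter ignores cross-covariances between state-action
  pairs.
* Aggregation weights, ε, and the diversity formula are package defaults
  where the source analyses leave them unstated.
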