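# Methods

This note records the modelling and numerical choices behind `actinf`: the
generative model and inference scheme, the synthetic-cohort generator, the
estimation machinery, and the known limitations of each.

## Task model

The T-maze trial has horizon T = 3 (an initial observation and two moves).
Hidden states are location × context, ordered location-major
(middle, left arm, right arm, cue) × (reward-left, reward-right); outcomes
are (middle, left±reward, right±reward, cue-left, cue-right); actions move
the agent to one of the four locations. The arms are absorbing: every
action applied to an arm state returns that state. No action changes the
context. The cue observation is deterministic and context-true; task
validity enters only through the arm outcomes, which reward with
probability `p_valid` (default 0.98, configurable — a conventional
"high-validity" value, not asserted as canonical) when the context matches
the arm and `1 − p_valid` otherwise.

Preferences derive from raw utilities (+4 reward, −4 unrewarded arm,
0 otherwise) through a log-softmax, so `exp(C)` is a proper prior over
outcomes and utility differences are preserved. With these utilities the
agent believes a reward is exp(4) ≈ 55 times more likely than a neutral
outcome.

**Policy set.** Raw enumeration gives 4² = 16 two-step action sequences, but
the four continuations from an absorbing arm are behaviourally identical;
keeping all of them would quadruple the prior mass on each one-armed gamble
relative to any distinguishable plan and (because pre-cue risk is exactly
symmetric under the ±4 utilities — see below) tips the first action toward
the arms. `build_tmaze` therefore collapses each arm-first family to a
single policy, leaving 10 distinguishable policies. `enumerate_policies`
remains the general lexicographic enumeration for arbitrary models.

## Inference within a trial

State estimation under each policy is exact forward–backward smoothing on
the trial chain with the observed outcomes clamped — the fixed point of the
variational update for a chain-structured posterior. Policies under which an
observation is impossible get probability zero (their belief slices are
recomputed with a floored likelihood so they remain simplexes); if every
policy consistent with the executed actions is impossible, a
degenerate-evidence error is raised rather than silently renormalizing.

Expected free energy is risk plus ambiguity accumulated over the remaining
time steps. A numerical floor `exp(−16)` inside every logarithm keeps
zero-probability preferences finite. A structural property of the ±4
utilities is worth recording: before the cue is seen, the predicted outcome
at an arm is a 50/50 coin flip whose mean utility equals the neutral
outcomes' utility, so pre-cue risk is *identical* for cue-sampling and
arm-gambling; the cue's advantage is purely epistemic (it avoids the arm's
outcome ambiguity, h(0.98) ≈ 0.098 nats per step). The margin is therefore
real but small at the first decision, and decisive only after the cue.

Precision follows the contract `β̂ = β + E_q[G]`, `γ̂ = α/β̂`, iterated
jointly with `q(π) = softmax(−F − γ̂G)` over policies consistent with the
executed actions. The fixed point must reach |Δγ̂| < 1e-4 within 16
iterations (it converges in 3–10 on the T-maze; failure raises), after
which iteration continues to 1e-12: the extra refinement costs microseconds
and makes the choice likelihood a smooth function of the hyperparameters,
which the finite-difference Newton scheme below requires. Note that this
contract bounds γ̂ above by the prior mean α/β = 1 and, because E_q[G]
carries the full preference-normalization baseline (≈ 8 nats at the first
decision of the T-maze), the realized γ̂ is ≈ 0.19 before the cue and
≈ 0.53 after it. Precision rising once the cue resolves the context is the
model's expression of reduced choice conflict; the iteration count at the
first decision is recorded as `rt_proxy`, a hardware-independent stand-in
for reaction time.

Action selection is the argmax of the marginal action probability by
default (ties to the lowest action index), making sessions reproducible
from the outcome stream alone; sampled selection is available behind a
flag and is what the cohort generator uses (below).

## Subject inversion

The objective model of choices treats log-scaling parameters
θ = (θ_β, θ_c) as free: `β ↦ β·exp(θ_β)` and `utilities ↦
utilities·exp(θ_c)` (re-normalized). θ = 0 reproduces the specified model.
Priors are N(0, 1/16) on each component — deliberately informative
shrinkage toward the reference model. The likelihood replays the recorded
session with outcomes clamped and scores the recorded actions against the
marginal action probabilities; since the agent does not learn across
trials, decisions with identical observation/action prefixes are evaluated
once and weighted by multiplicity (an order-of-magnitude saving at 128
trials). Recorded actions with probability below exp(−16) contribute the
floor and are counted in the posterior's diagnostics.

Optimization is Newton ascent with central finite differences (step 1e-3 on
θ), step-halving line search, convergence at |ΔF| < 1e-3 or 32 iterations
(typically 3–6), and the posterior covariance taken as the inverse negative
Hessian, symmetrized and ridge-regularized (escalating from 1e-6·I) to
positive definite. The free energy receives the Laplace volume correction
`(d/2)·log 2π + ½·log det Cp` so that it is comparable across models. The
posterior correlation between θ_β and θ_c (≈ 0.6–0.7 on default sessions)
is exposed as a conditional-dependency diagnostic: both parameters sharpen
choices, and they are separable mainly because the first decision's logits
are invariant to the utility scale while the second decision's are not.

## Group level

The second-level model is `θ_i = X_i·β_g + ε_i` for the selected parameter,
with X = [1, ±1·group]. The between-subject variance is the first-level
prior variance divided by the within:between ratio (default 16), scaled by
`exp(−h)` with a log-precision hyperparameter h ~ N(0, 1/16). The
second-level free energy is the sum over subjects of the Bayesian model
reduction (BMR) log-evidence change when the subject's original prior on
the modelled parameter is replaced by the empirical prior `N(X_i·β_g,
σ_b²)` — no subject is ever refitted — plus the shrinkage priors on β_g
(variance 1/16 per effect, matching the first level for scale coherence;
configurable, as no canonical value exists) and h. The same Newton
machinery maximizes it over (β_g, h).

BMR itself is the closed-form Gaussian identity: with prior (m₀, P₀),
posterior (m, P) and reduced prior (m_r, P_r), the reduced posterior has
precision `P_q = P + P_r − P₀` and the evidence changes by
`½(quadratic + log-determinant)` terms; it is exact for Gaussian pairs and
verified in the tests against a from-scratch conjugate refit.

Model comparison switches design columns off by collapsing their
second-level prior variance to 1e-8 and re-scores the fitted second level
by BMR; posterior model probabilities are the softmax of the four free
energies under uniform model priors, and the Bayesian model average is the
probability-weighted moment-matched mixture. Because the design codes the
group indicator ±1, the *group difference* in the parameter is twice the
indicator coefficient; `PEBResult.group_gap` reports it on that scale. A
classical pooled-variance two-sample t test (two-sided, single planned
contrast, no multiplicity correction) runs alongside on the first-level
posterior means — deliberately *not* on the empirical-prior updated means,
which are shrunk toward the group means encoded in the design matrix and
would make the test circular.

Leave-one-out classification refits the PEB model on N − 1 subjects, then
evaluates the held-out subject's BMR evidence under the empirical prior
implied by each indicator level (variance = between-subject variance plus
the propagated uncertainty of β_g) and normalizes the two evidences to a
Bernoulli posterior; accuracy is scored at threshold 0.5. Folds are
subjects, never trials.

## Synthetic cohorts

The generator reproduces the study conditions: two groups of eight
subjects, 128 trials each, initial states at the middle location with
contexts drawn 50/50, subject-level `θ_β ~ N(offset_g, exp(−2))` (log
precision 4 → sd ≈ 0.135), group offsets {0, +0.25}. The positive offset
raises the Gamma rate in group 2, lowering its expected precision so that
the "patient" group behaves more stochastically and earns less reward —
the direction in which the latent hyperparameter produces an observable
deficit. Each subject has a counter-based RNG stream, so enlarging the
cohort never perturbs existing subjects.

Cohort subjects *sample* their actions from the marginal action
probability. This is the one place the package departs from the argmax
default: a cohort of argmax agents would emit identical choice sequences
whatever their θ_β, leaving nothing for inversion to recover; between-
subject differences in the precision hyperprior are expressed in choice
stochasticity or not at all.

## What passing tests do and do not show

The simulator generates exactly the data the inversion assumes (same model
family, no learning, no lapses, no drift), so parameter-recovery results
here are an upper bound on what real behaviour would allow. Two
attenuations relative to an idealized observer are intrinsic and
documented rather than patched:

1. Under the precision contract above, γ̂ varies only between ≈ 0.19 and
   ≈ 0.53 across the trial regardless of θ_β, so a 128-trial session
   carries limited Fisher information about the precision hyperprior.
   First-level estimates shrink by roughly 0.4–0.6 toward the prior mean,
   the recovery correlation over 16 subjects is ≈ 0.55–0.85 by seed, and
   the two-sample t statistic for the one-quarter offset centres near 2
   rather than in the clearly-significant range a sharper likelihood would
   give. The hierarchical (PEB) difference estimate largely undoes the
   shrinkage — it pools the implied per-subject likelihoods, not the
   shrunken means — and brackets the simulated 0.25 offset.
2. For the same reason the second-level model comparison is conservative:
   with zero simulated difference the null model is reliably the most
   probable (posterior ≈ 0.5) but difference-containing models retain
   ≈ 0.25–0.35 of the mass, and leave-one-out accuracy under the default
   effect is ≈ 0.6–0.9 by seed.

## Problem sizes and determinism

Default analyses run the full study conditions (16 subjects × 128 trials;
a complete pipeline takes a few seconds on one core thanks to the
unique-decision cache). The test suite uses reduced cohorts (2 × 4
subjects, 64 trials) for repeated-cohort properties and the full size for
the study-condition checks. All randomness flows from
`numpy.random.default_rng` seeded from a single integer; every report,
posterior and CSV regenerates bit-identically from (spec, seed, config).

## Known limitations

No learning of A/B/D concentration parameters, no habit pathway, no
simulated neuronal responses, single-factor hidden states, two-level
hierarchy only, binary group designs only, and a single precision
component for the second-level random effects. The exact update schedule
of the reference variational scheme this package parallels is not public;
only the convergence contracts stated above are normative here.
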