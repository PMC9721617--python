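# Methods

This note documents the models, the sampler, the synthetic-data generator,
and the numerical and design choices behind them. It states no empirical
result that the test-suite or `scripts/acceptance.py` does not itself
compute.

## Task environment

The environment is a deterministic two-step task: two first-stage states ×
two actions, a fixed action→planet map (each state reaches both planets;
the default map anti-aligns action slots across states so that "same
response key" and "same planet" are distinct notions), and per-planet
integer payoffs in [−4, 5].

**Reward walks.** Each planet's payoff follows a latent continuous Gaussian
random walk with per-trial increment SD equal to the scheduled drift level
(0.5, 1, or 2, laid out in contiguous blocks of a seeded permutation; six
blocks per 200-trial session by default). The walk "bounces" off the
bounds by iterated reflection, `x → 2·bound − x`, applied to the latent
value; the delivered reward is the latent rounded to the nearest integer.
Reflection (rather than clipping) preserves the walk's variance near the
bounds; it also induces mild mean-reversion toward the interval centre,
which matters for one behavioural consequence noted under *Limitations*.
The two planets' walks are independent. The latent starts uniform within
the bounds.

**First-stage sequence.** Pseudo-random with a configurable probability
(default 0.5) of repeating the previous state, keeping the two states
near-equally frequent.

**Stay coding.** A trial t ≥ 2 is a "stay" when the chosen spaceship flies
to the same planet as the previous trial's choice — planets, not stimuli,
are compared, so the coding is invariant to stimulus relabelling and well
defined when the first-stage state changes. One Euro-cent bookkeeping rule
(4 cents/point) converts totals to payouts.

## Choice models

All variants share the softmax choice rule over
`Q = ω·Q_MB + (1−ω)·Q_MF` with inverse temperature η ≥ 0, computed in a
max-subtracted, overflow-safe form. Values start at zero, so the first
trial of a session contributes exactly log ½ for non-sticky models — a
contract the tests pin.

* **M1**: after reward r, `Q_MF(chosen) = r` and the other three
  model-free entries multiply by (1−γ); the reached planet's value
  `Q2 = r`. The model-based value of every spaceship is *defined* as the
  value of the planet it flies to, `Q_MB(a,s) = Q2(map(s,a))`, which is how
  experience transfers to the never-chosen spaceship of the other state.
  The unvisited planet's value persists undecayed (the printed equations
  shrink only model-free entries; a decaying-Q2 alternative was considered
  and not implemented — no equation supports it).
* **M1-sticky** adds `ρ·resp(a) + π·stim(a)` to the choice values, where
  `resp` marks the action slot taken on the immediately preceding trial
  (regardless of state) and `stim` the previously chosen spaceship; both
  indicators are zero on trial 1.
* **M2/M3**: SARSA-style TD with the stage-1 prediction error computed
  from the planet value *before* the stage-2 update
  (δ₁ = Q2(s₂) − Q_MF(s₁,a); Q_MF += α₁δ₁), then the stage-2 step
  Q2 += α₂δ₂ with δ₂ = r − Q2, and finally the eligibility-trace step
  Q_MF(s₁,a) += λα₁δ₂. M3 ties α₁ = α₂. The update ordering is fixed
  and pinned by an exhaustive oracle test (all 2⁵ choice sequences of a
  5-trial session, four model variants, agreement to 1e−10); no
  alternative-ordering switch is exposed.

The likelihood/simulation inner loops are numba-compiled
(`twostep._kernels`); a readable pure-Python mirror (`engine="python"`, and
the step-functions `m1_update`/`td_update`/`mixed_value`) is asserted equal
to the kernels in the tests.

## Hierarchical model

Per subject i and native parameter p, estimation-space latents
`(p0'_i, Δp'_i)` stack into θ_i ∈ R^D (D = 6 for M1, 8 for M3, 10 for
M2/M1-sticky):

    θ_i ~ MVN(μ + A_i β, diag(σ) R diag(σ))

where A_i adds the subject's drug-arm coefficients (and, optionally, a
high-serum coefficient, coded 1 for high-serum amisulpride subjects and 0
otherwise) to the session-difference components. Session-1 native
parameters are transforms of the baselines, session-2 of baseline +
difference: probit (Φ) for [0,1] parameters, exp for η, identity for ρ, π.
Hyper-priors: μ ~ N(0,1), σ ~ HalfNormal(0,1), R ~ LKJ(2), β ~ N(0,1.5).
Subjects missing a session contribute only the observed session's
likelihood. Effect sizes standardize β by the pooled SD
√(σ²_baseline + σ²_difference), draw-wise. Summaries are posterior means,
central (equal-tailed) 95% intervals, and one-sided tail probabilities.

### Sampler

No probabilistic-programming backend is used; the posterior is drawn by a
Metropolis-within-Gibbs scheme built from four moves per sweep:

1. **Subject blocks** — vectorized Gaussian random-walk Metropolis on each
   θ_i (two scans per sweep). Proposal covariances are per-subject
   empirical covariances (Haario-style) with Robbins–Monro-tuned scales,
   adapted during warmup only and frozen afterwards, so the post-warmup
   kernel is time-homogeneous. Chains start from per-subject penalized-ML
   values (Nelder–Mead with a unit-normal penalty), jittered per chain.
2. **(μ, β)** — exact conjugate MVN Gibbs draw: given Σ and the latents,
   the model is linear-Gaussian in (μ, β).
3. **(σ, R)** — univariate slice sampling in an unconstrained space:
   log σ, and canonical partial correlations (CPCs, tanh-transformed) for
   R. Under LKJ(η) the CPCs are independent scaled-Beta variables, so the
   prior density in this space is exact and factorized. The conditional
   depends on the latents only through their residual scatter matrix,
   precomputed once per sweep, making each slice evaluation O(D³).
4. **Interweaved non-centered (ASIS) moves** — scalar Metropolis updates
   of each log σ_d (rescaling that latent column about its mean), each
   μ_d (translating the column), and each β (translating the affected
   arm's difference column), all holding the standardized residuals fixed.
   The MVN-prior and Jacobian terms cancel exactly, leaving likelihood ×
   hyper-prior ratios. These moves break the funnel coupling that makes
   centered Gibbs mix slowly in the hyper-SDs of weakly identified
   dimensions (notably the session differences of γ). This
   centered/non-centered interweaving is the Gibbs-sampler analogue of the
   non-centered parameterization used with Hamiltonian samplers.

Correctness is validated by an exact prior-recovery test: single-trial M1
sessions make the likelihood constant, so the fitted posterior must equal
the prior — μ moments, the HalfNormal σ mean √(2/π), the β scale 1.5, and
the LKJ(2) marginal correlation variance 1/(2a+1) with a = 2 + (D−2)/2 are
all checked against their analytic values. A term-by-term oracle test pins
the joint log density itself.

Defaults follow the 4-chain, 3000-iteration (1000 warmup) convention;
split-R̂ and ESS are computed with arviz and any group-level quantity with
R̂ ≥ 1.01 is surfaced in the result's `warnings` (as is a low
subject-block acceptance rate — the Metropolis analogue of a
divergent-transition warning, which does not exist outside Hamiltonian
samplers). Short "fast-mode" chains (e.g. 2 × 450) used in the replicate
tests mix well enough for point estimates and intervals but can leave
R̂ above 1.01 for the slowest hyper-parameters; those warnings are
expected there.

## Stay regression

`build_stay_table` codes stays with `prev_points` on its raw integer
scale (the per-point odds are the published quantity), `diff_state` = 1
when the first-stage state differs from the previous trial, and `session`
∈ {0, 1}. The population design is the full factorial
prev_points × diff_state × session × drug (placebo reference; the serum
variant splits the amisulpride dummy at the high/low serum boundary); the
within-subject terms form correlated random effects (full factorial by
default; a "narrow" option restricts them to intercept, previous-state and
session slopes, mirroring a plausible reduced specification). Priors:
N(0,3) slopes, Student-t(3,0,10) intercept, Half-Cauchy(0,2) random-effect
SDs, LKJ(2).

The sampler reuses the Gibbs skeleton with one-step IRLS Gaussian
approximations as proposals for both the fixed-effect block and each
subject's random-effect block (Gamerman-style; the reverse-move
approximation enters the Metropolis–Hastings correction, so the exact
Student-t intercept prior and Bernoulli likelihood are targeted). The
random-effect covariance uses the same slice-in-CPC-space move with the
Half-Cauchy SD prior.

`link_slopes_to_params` extracts each subject's session-2 previous-points
slope (same-state) and different-vs-same interaction slope — fixed terms
relevant to the subject's group plus their random effects — standardizes
slopes and model parameters, and fits two ordinary least-squares models
predicting the slopes from (ω, γ, η), with classical 95% intervals.
Zero-variance predictors or slopes are reported as degenerate rather than
fitted.

## Synthetic cohorts

`CohortSpec` fixes the study conditions: arm sizes, 200 trials × 2
sessions, drift levels {0.5, 1, 2}, MVN latents with drug shifts on the
difference components. The study-sized fixture uses arms 35/38/39
(placebo/amisulpride/naltrexone), an amisulpride shift of +0.8 on Δω′
(the scale of the reported estimate), and an 18-high/14-low serum split
among 32 serum-measured amisulpride subjects. Default hyper-values
(μ_ω0′ = 0, μ_γ0′ = −0.5, μ_η0′ = 0.3, zero difference means; baseline SDs
0.8, difference SDs 0.5; R with −0.3 between each parameter's baseline and
difference, emulating regression to the mean) are fixture choices on the
scale typical of this literature, not estimates. Serum groups exist only
in the amisulpride arm. Every subject-session gets independent reward
walks and first-state sequences (the original design reused shuffled
trajectories across participants; independence is simpler and
statistically conservative). Cohort generation is byte-reproducible from
the master seed.

**What the generator does not emulate.** Human data features outside its
scope: missed/timed-out trials, order and practice effects, within-pair
response biases beyond the sticky variant, and any misfit of the M1 family
itself. Passing recovery tests therefore demonstrate that the inference
machinery is correct and calibrated *under the model*, not that the model
is true of human behaviour.

One divergence deserves emphasis: in human data, more model-based subjects
earned more money. Under the M1 generative process this does *not*
reproduce — simulated earnings peak at intermediate ω and decline toward
ω = 1 at higher η, because the γ-forgetting of unchosen options acts as
implicit mean-reversion toward the reward-walk centre (an effect of the
bouncing bounds), so a model-free component improves the handling of stale
values. The ω–earnings correlation is a property of human behaviour, not
of the idealized learner; tests assert only the design-goal comparison
(a high-precision model-based agent outearns uniform-random play).

## Model evaluation

* **Trial-wise LOO**: per-draw, per-trial log-likelihoods (columns sum to
  the fit's total choice likelihood, asserted to 1e−8) feed arviz's
  PSIS-LOO; LOOIC = −2·elpd. Pairwise elpd differences use the SE of the
  paired pointwise differences. Pareto-k values above 0.7 are flagged;
  first-trial columns are constant across draws (log ½), for which the
  Pareto fit is undefined — those k values are reported as-is and are
  harmless because the pointwise elpd is exact there. The PSIS-LOO
  estimate is validated against a closed-form conjugate-Gaussian LOO
  oracle.
* **Pseudo-BMA weights**: Bayesian-bootstrap (Dirichlet(1) over trials,
  1000 replicates, seeded) softmax of total elpd, averaged over
  replicates.
* **Predictive accuracy**: per draw and trial, the predicted choice is the
  higher-valued action (exact value ties credit ½); accuracies average
  over draws and trials within subject; a probability-averaging rule is
  available behind a flag. Default draw budget 8000, configurable.
* **Recovery harness**: simulate → fit → per-latent Pearson r, bias,
  95%-interval coverage, and injected-vs-recovered group coefficients.
* **Posterior predictive check**: each subject re-simulated at
  posterior-mean latents (transform of the mean, applied per session) on
  fresh seeded environments; binned stay-probability curves (five reward
  bins, display only) and optionally a refitted stay regression are
  compared side by side.

## Problem sizes in the test-suite and acceptance script

Replicate-based checks run at deliberately reduced scale so the whole
pipeline stays desk-scale: parameter recovery at 50 subjects × 200 trials
× 2 sessions (2 chains × 700); drug-effect recovery and nulls at 12/arm ×
150 trials over 20 replicates each (2 × 350); model-comparison
self-consistency at 24 subjects × 120 trials over 20 replicates of three
model fits (2 × 300). At these sizes the recovered drug coefficient is
visibly shrunk toward zero (posterior means ~0.3–0.6 against an injected
0.8) — expected behaviour of a hierarchical posterior when individual
session differences are weakly identified — while sign and interval
calibration hold, which is what the replicate tests assert.

## Known limitations

* Group-level R̂ < 1.01 requires full-length chains; fast-mode fits trade
  that for runtime and say so in `warnings`.
* Session differences of γ are weakly identified at these trial counts;
  their recovery correlations are low and their hyper-SD mixes slowest.
* The Gamerman proposals assume the logistic conditional is
  well-approximated by one IRLS step; with separation-prone tables the
  acceptance rate drops (surfaced as a warning) rather than failing.
* Reproducing the published human-data estimates requires the deposited
  dataset and multi-hour chains; nothing in this repository substitutes
  for it.
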