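# Methods

This note documents the sampling machinery, the statistical models, the
synthetic-data generators and the numerical choices behind `lapnuts`, in
enough detail to reproduce or re-derive every component.

## Model contract

A model is an unconstrained log-posterior density ℓ(q) with an analytic
gradient, plus per-parameter metadata (`ParameterSpec`: name, bounds,
fixed/random role, constrained-scale init). All Jacobian terms live
inside ℓ, so the samplers are geometry-agnostic. Gradients are hand-coded
per model; central finite differences (step 1e-5, relative tolerance
1e-4) are a verification oracle only (`check_gradient`), never the
sampling path — automatic differentiation is deliberately out of scope.

Bounded parameters map through the identity / log / logit bijections with
the log-Jacobian added to the density (`make_bounded_model`). The
two-sided transform is the logistic bijection — a dialect choice made for
monotone C∞ behavior and a simple Jacobian; no bit-compatibility with any
other system's interval transform is attempted. Constrained values that
land numerically on a bound are clamped into the open interval by a
relative 1e-12 to keep round trips finite.

## NUTS transition

The slice-condition doubling variant is implemented: momentum p ~ N(0, M)
is refreshed fully each transition, a slice variable u ~ Uniform(0,
e^{−H₀}) is drawn, and the trajectory doubles forward or backward until
either end turns back (strict inequality: (q⁺−q⁻)·M⁻¹p < 0; a zero
projection continues) or a state's energy error exceeds Δ_max = 1000 (the
conventional divergence constant). The proposal is uniform over
slice-valid states; `accept_stat` averages min(1, e^{H₀−H}) over every
leapfrog state of the trajectory. The multinomial variant, exhaustive
termination criteria, Riemannian metrics and step-size jitter are all out
of scope. `max_treedepth` defaults to 12 (a generous cap; the first
subtree has depth 0, so `max_treedepth=0` forces exactly one leapfrog
step). One gradient evaluation per leapfrog step, plus one at
initialization.

The metric stores the *inverse* mass matrix (the posterior-covariance
scale on which warmup estimates it); kinetic energy is ½ pᵀM⁻¹p and
constructors accept either representation.

## Warmup adaptation

The schedule follows the standard three-phase design: an initial buffer
(75 iterations) of step-size-only adaptation, doubling "slow" windows
(base 25) in which draws accumulate for metric estimation, and a terminal
buffer (50). A window whose doubled successor would overrun the slow
phase is extended to absorb the remainder; warmups too short for the
buffers shrink them proportionally around a single window. At each window
end the inverse mass is re-estimated as the regularized variance
(diagonal) or covariance (dense) of the window draws,
(n/(n+5))·sample + (5/(n+5))·1e-3·I.

Step size adapts by dual averaging toward the target acceptance δ
(default 0.8) with the conventional constants γ=0.05, t₀=10, κ=0.75 and
anchor μ = log(10·ε₀), where ε₀ comes from the double/halve search for a
one-step acceptance of ½. Dual averaging restarts (with a fresh ε₀) at
each metric update **except the last**. This exception is a deliberate
design choice on a genuinely open point: the final window's metric
revision is typically small, and a fresh restart would leave only the
50-iteration terminal buffer to re-converge — its κ-weighted average is
then dominated by the restart transient, freezing a step size visibly
below the optimum (measured as post-warmup acceptance ≈ 0.87 instead of
0.8 on an isotropic 10-d Gaussian). Letting the long-running averaged
state continue through the terminal buffer recovers the 0.8 target within
±0.02. The sampling step size is exp(log ε̄) frozen at the end of warmup.
A user-supplied dense metric (e.g. the `find_mode` covariance) bypasses
metric adaptation; a user-supplied step size bypasses dual averaging.

## Random-walk Metropolis

A non-adaptive Gaussian-proposal Metropolis sampler with scale
2.4/√d around a supplied covariance (mode-based by default, mirroring the
historical mode-centred workflow). Its role is cross-validation: on every
packaged analytic target, NUTS and RWM moments must agree within joint
3·MCSE (MCSE from ESS). This is the package's primary cross-sampler
equivalence oracle.

## Laplace marginalization

For a joint density ℓ(θ, u) with designated random-effect coordinates u,
the marginal model evaluates

  log p(θ) = ℓ(θ, û) + (n_u/2)·log 2π − ½·log det H,

with û the Newton mode of ℓ in u at fixed θ and H = −∂²ℓ/∂u²(θ, û). The
inner Newton uses Cholesky solves, halving line search on non-increase
(20 halvings max), tolerance 1e-8 on the max-norm gradient, 100
iterations max; a non-SPD terminal Hessian or failed line search reports
non-convergence, the marginal density becomes −∞ and the outer transition
is treated as divergent. H is analytic where the model provides a
`uu_hessian` (all packaged GLMM-family models do — it is a cheap
weighted cross-product there); central differences of the gradient are
the fallback. log det H reuses the final Cholesky factor.

The outer gradient is central finite differences of the marginal density
(step 1e-5·max(1, |θᵢ|)), warm-started from the previous inner mode; cold
starts begin at zero, the prior mean on the non-centered scale. Implicit
differentiation through the inner optimum would be cheaper per evaluation
but model-specific; at the case-study scale (≤ 10 fixed effects) the
finite-difference route costs 2·dim(θ) extra inner solves per gradient,
each converging in 1–3 warm-started Newton steps. Warm- and cold-started
solves agree in marginal density to 1e-8 (tested).

Because the Laplace approximation is exact for Gaussian integrands, the
linear-Gaussian random-effects model is the keystone test: the marginal
must match the closed-form N(y; θ1, σ_y²I + σ_u²11ᵀ) density to 1e-8, and
full-MCMC versus marginalized NUTS must give indistinguishable
fixed-effect posteriors.

## The two-version audit

`compare_versions` runs NUTS on the joint model and on the marginal
model, thins each posterior by its own worst-parameter stride
round(n/min-ESS) and truncates to the common length (comparisons at
unequal effective sample sizes are misleading when mixing rates differ),
then compares each fixed effect by sorted-pair QQ points and a two-sample
Kolmogorov–Smirnov test. The visual QQ comparison is the field's usual
presentation; the numeric flag — any KS p-value below a
Bonferroni-corrected family level α = 0.01 — is this package's
operationalization of "the two versions differ". The two runs may use
different chain counts/lengths (the joint run is cheap per iteration, the
marginal run is not); the ESS matching is what keeps the comparison fair.

## Case models

**Wildflower** (binomial GLMM): success probability
logistic(β₀ + (β_size + s_i)·x + y_j + p_i) with year intercepts y_j,
plant intercepts p_i and plant slopes s_i — three random-effect
components, the plant-indexed pair crossed with year through the
plant×year observation grid. Parameters: β₀, β_size, three log-scale
hyper-SDs, then the three raw vectors (5 + n_years + 2·n_plants total).

**Swallows** (CJS mark–recapture): survival logit
b₀ + b_env·env_t + b_size·size_i + brood and year effects; detection
logit a₀ + a_eff·effort_t + brood effect. The latent alive states are
marginalized analytically with the χ recursion
χ_t = (1−φ_t) + φ_t(1−p_{t+1})·χ_{t+1} (a discrete latent cannot ride in
a gradient-based sampler), giving a smooth marginal likelihood whose
gradient is back-propagated through the recursion. The packaged fixture
has 5 fixed regression effects and 172 random effects decomposed as 84
brood-on-survival + 84 brood-on-detection + 4 year-on-survival — the
total is a known quantity but its decomposition is not published, so this
split is an explicit, documented assumption of the fixture. The three
hyper-SDs are counted separately from the 5 fixed effects.

Both case models default to non-centered random effects (effect =
σ·raw, raw ~ N(0,1)), which empirically produces fewer divergences than
the centered form at δ = 0.8 (tested); centered variants are available
for that comparison. Hypervariances are sampled as log σ with the +log σ
Jacobian in the density. Priors: N(0, 5²) on fixed regression effects and
half-N(0, 5²) on each σ — the half-normal is placed on the σ scale
(rather than on log σ directly) precisely so that the log-space Jacobian
adjustment is a real, testable part of the density. Priors are
configurable via `prior_sd`.

Small auxiliary random-effect models validate the Laplace machinery:
linear-Gaussian (exactness), Poisson log-normal (adaptive Gauss–Hermite
quadrature oracle), and a Bernoulli random-intercept GLMM (the known
Laplace failure regime).

## Synthetic-data generators

The generators are the package's study conditions, not test scaffolding:

- `gen_wildflower` defaults: 40 plants × 6 years, 4 trials per
  plant-year, β₀ = −0.5, β_size = 0.8, σ_year = 0.7, σ_plant_int = 1.0,
  σ_plant_slope = 0.5; size covariate standardized to mean 0, sd 1.
  Moderate binomial information per observation and realistic
  hypervariance magnitudes for a perennial-plant flowering study.
- `gen_swallows` defaults: 84 broods × 2 individuals over 10 occasions in
  4 years; survival intercept 1.2 and detection intercept 0.6 on the
  logit scale (survival ≈ 0.77, detection ≈ 0.65 at covariate means),
  RE scales 0.5/0.7/0.3; release occasions uniform; covariates
  standardized. Histories are truncated before first capture (CJS
  conditioning).
- `gen_bernoulli_glmm` defaults: 40 groups × 2 Bernoulli observations,
  β₀ = 0, σ = 1.5 — deliberately the sparse-information regime where the
  Laplace approximation is known to fail, sized as a realistic small
  field study.

What the generators do **not** emulate: overdispersion beyond the model,
missing covariates, temporary emigration or tag loss (swallows),
unbalanced designs, or model misspecification of any kind. Passing tests
therefore demonstrate correctness of the samplers and estimators *under
the model*, not robustness of the models to real field data.

## Diagnostics

Split R-hat halves each chain and computes
sqrt(((n−1)/n·W + B/n)/W); zero within-chain variance yields NaN with a
warning. ESS splits chains, computes per-chain autocovariances by FFT,
combines them with the between-chain term (ρ̂_t = 1 − (W − mean
autocovariance)/var⁺), applies Geyer's initial monotone positive sequence
to the paired sums, and returns mn/τ capped at twice the total draw
count; strongly antithetic chains legitimately exceed the nominal count.
Both estimators are cross-checked two ways: against shipped fixtures
whose reference values were precomputed with direct-sum O(n²)
autocovariances and an explicit Geyer loop
(`tests/fixtures/diag_reference.json`, generator alongside), and against
an independent reference implementation (arviz) within 2%. The
rank-normalized R-hat refinement is out of scope.

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to give each statistical check
real power at desk scale: the adaptation target uses the canonical
3×2000-iteration default; the audit's failure-detection check runs 10
simulated datasets with a long cheap joint run (4×4000) against a shorter
marginal run (2×2200) before ESS matching; parameter recovery refits 20
datasets at 1200 iterations each. Seeds derive from (global seed, chain
index) via `numpy.random.SeedSequence`, so chains are reproducible
regardless of serial/parallel execution or scheduling. Degenerate inputs
are handled explicitly: metric windows with fewer than 5 draws keep the
previous metric; unconstrained coordinates beyond ±200 (where a
log-scale parameter's exp would overflow) evaluate to −∞ and surface as
divergences; χ-recursion underflow at saturated logits does the same.

## Known limitations

- The outer Laplace gradient is O(dim θ) inner solves; tens of fixed
  effects would warrant implicit differentiation.
- The inner Newton assumes a concave (unimodal) conditional for u; the
  packaged GLMM-family conditionals are log-concave, but multimodal
  conditionals would silently find a local mode.
- Dense-metric estimation is O(d²) memory and is regularized but not
  shrunk adaptively; very high-dimensional dense adaptation is not the
  intended use.
- The audit's KS flag depends on the matched effective sample size: a
  negative result bounds the discrepancy only at the resolution the run
  affords.
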