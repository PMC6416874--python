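# Methods

## Model and hypotheses

`regpower` addresses planning of regression model-validation studies:
testing whether newly collected data are compatible with a previously
published formula, as opposed to selecting or fitting a model.  The data
model is ordinary linear regression with Gaussian errors,

    Y_i = β_I + X_i' β_S + ε_i,    ε_i ~ iid N(0, σ²),

and the validation question is the *joint* general linear hypothesis
H₀: (β_I, β_S) = (β_I0, β_S0) — both the intercept and every slope at
once, since prediction accuracy depends on the coefficients jointly.
The test statistic is the likelihood-ratio F

    F = { (β̂ − θ)' (X'X) (β̂ − θ) / (p+1) } / σ̂²,   σ̂² = SSE / ν,

with ν = N − p − 1, rejected at level α when F strictly exceeds the
central-F upper-α quantile.  For p = 1 this is algebraically identical
to the form written in terms of W_X = (X'X)⁻¹ with
W11 = 1/N + X̄²/SSX; the package computes the general quadratic form for
all p and retains the p = 1 W-form as a test oracle only.

## Conditional vs unconditional power

Given observed predictors, F has a noncentral F distribution with
noncentrality

    Δ = { N (β_ID + β_SD' X̄)² + β_SD' A β_SD } / σ²,

a function of the data only through the predictor mean X̄ and the
centred scatter A.  Conditional power (`power_conditional`) is the
noncentral-F tail at this Δ — appropriate once the design is realized.

At the planning stage the predictors are unknown.  Treating them as
random draws from N_p(μ_X, Σ_X), X̄ and A are independent with normal
and Wishart distributions, and Δ reduces to a two-variable mixture

    Δ = { N (a + bZ)² + d K } / σ²,
    Z ~ N(0,1),  K ~ χ²(κ),  κ = N − 1,
    a = β_ID + β_SD'μ_X,  d = β_SD' Σ_X β_SD,  b = √(d/N).

Unconditional power Ψ (`power_exact`) is the expectation of the
conditional tail probability over (Z, K).  The mean-substitution
approximation (`power_approx`) replaces each X_i by μ_X, yielding a
single noncentral F with Δ_C = N a²/σ².  Since it discards the
nonnegative d-term, Ψ_C ≤ Ψ always, strictly whenever d > 0 — the
approximation systematically understates power and oversizes studies.
The per-observation effect sizes Δ*/N → (a² + d)/σ² (exact) and a²/σ²
(approximate) summarize detectability and drive the no-finite-solution
guard in the sample-size search.

## Numerical evaluation of the double expectation

The default scheme (`mixture_1d`) collapses the two-dimensional
expectation analytically.  Because N(a + bZ)² = d (Z + a/b)² with
Nb² = d, and (Z + a/b)² is a 1-df noncentral χ² with noncentrality
λ = Na²/d independent of K, the combined mixing variable

    W = N(a + bZ)²/d + K  ~  χ'²(N, λ)

is a single noncentral χ² with N degrees of freedom, and

    Ψ = ∫ P{ F(p+1, ν, (d/σ²) w) > F_crit } dF_W(w).

This collapse is an implementation identity, not part of the derivation,
so it is verified in the test suite against a direct two-dimensional
rule (`hermite_x_chisq_2d`: 160-node probabilists' Gauss–Hermite over Z
crossed with a 512-node Gauss–Legendre rule on the probability scale of
K); the two schemes agree to better than 1e-7 across a 108-point stress
grid.  A plain `monte_carlo` scheme over (Z, K) exists for loose sanity
checks.

Numerical choices:

* The mixing distribution is truncated to its [1e-10, 1 − 1e-10]
  quantile range; the trimmed tails are added back at their monotone
  endpoint bounds (the F tail probability is increasing in w), and the
  2e-10 trim enters the reported error estimate.
* Adaptive quadrature (QUADPACK) to absolute tolerance 1e-8 by default —
  printed benchmark values carry 4 decimals, so 1e-8 leaves rounding
  unambiguous.  If the error estimate exceeds the tolerance the routine
  raises a convergence error rather than returning a silently inaccurate
  value.
* d = 0 (no slope difference, or slope difference orthogonal to Σ_X) is
  handled in closed form: Δ is the constant Na²/σ² and no integration is
  performed.  This also makes the exact and approximate methods agree to
  1e-10 in that branch, as they must.
* Zero noncentrality uses the central-F survival function directly so
  null power equals α to machine precision.
* Rejection uses strict inequality; ties have probability zero.
* The Gauss–Hermite node count is capped at 256 (the weight computation
  overflows beyond that); the default 160 × 512 rule leaves the 2-D
  scheme's self-estimated error well under 1e-6.

## Sample-size search

`min_sample_size` returns the smallest integer N whose power (exact or
approximate) reaches the target.  The search doubles N geometrically
from the floor N₀ = p + 3 to bracket the target, then bisects to the
minimal integer — result-identical to a linear incremental scan because
power is nondecreasing in N at fixed effect, but O(log N) in
evaluations.  The floor guarantees ν ≥ 2 and κ ≥ 2 so every mixing
distribution is proper.  Power is compared to the target with no epsilon
slack; the 1e-8 quadrature tolerance makes 4-decimal boundary cases
deterministic.  The evaluation at N − 1 (the minimality witness) is kept
in the returned search trace.  A relative threshold (1e-12 of the exact
effect size) guards the zero-effect case, where float cancellation in
a = β_ID + β_SD'μ_X can leave a ~1e-16-scale residue whose square would
otherwise send the search toward astronomically large N.

## Monte Carlo engine

`simulate_power` draws, per replicate, a fresh predictor matrix from the
population and fresh Gaussian errors, runs the joint F test, and counts
rejections — the full data-generating process, which is what makes it an
independent oracle for the analytic formulas rather than a re-evaluation
of them.  Replicates use independent child streams spawned from the
master seed (`SeedSequence.spawn`), so replicate k is reproducible in
isolation; the F statistics themselves are computed with batched linear
algebra across replicates.  The reported Monte Carlo standard error is
the binomial √(p̂(1−p̂)/R).

Predictor families beyond the normal are provided for robustness
studies, each the unique affine standardization to the requested mean
and variance: exponential X = μ + σ(E−1); gamma(2,1)
X = μ + σ(G−2)/√2; Laplace X = μ + σL/√2; uniform
X = μ + σ√12(U−½).  Non-normal families are univariate (the analytic
theory and the robustness question are posed for p = 1).

`run_validation_study` sweeps a grid of configurations: per cell it
finds the exact method's minimal N for the cell's target, evaluates both
analytic powers there, and simulates empirical power at the same N.  The
N and analytic columns are deterministic (seed-independent); errors are
reported as analytic estimate minus simulated power.  The standard
nine-cell benchmark grid (`coefficient_shift_grid`) shifts both
coefficients by d off the null (0, 1) with σ² = 1, μ_X ∈ {0, 0.5, 1},
σ_X² ∈ {0.5, 1, 2}, α = 0.05, target 0.90 — the configuration space a
validation study of a calibration-type formula plausibly occupies.

## What the generator does and does not emulate

Synthetic data have exactly iid predictors, homoscedastic independent
Gaussian errors, and no measurement error in X.  Passing tests therefore
demonstrate the correctness of the power calculus under its own
assumptions — not robustness to heteroscedasticity, serial correlation,
predictor measurement error, or non-iid sampling, none of which are
modelled.  Predictor non-normality *is* exercised, with a known
limitation: under exponential predictors standardized to μ_X = 0,
σ_X² = 2, the true unconditional power at the normal-theory N = 53 is
≈ 0.873 against the normal-theory 0.905 — a deviation of ≈ 0.032,
established semi-analytically by averaging the exact conditional power
over simulated (X̄, SSX) draws.  Strong skewness at small N and large
predictor variance is where normal-theory planning is least trustworthy;
the milder gamma, Laplace and uniform shapes stay within ~0.02.

## Problem sizes used in the shipped studies

The validation studies shipped with the package use 10,000 Monte Carlo
replicates per cell (binomial SE ≈ 0.003 near power 0.9), the
end-to-end analytic-vs-simulation oracle uses 200,000 replicates per
configuration, and the conditional-power oracle uses 10⁶ error redraws
on a frozen design — sizes chosen so binomial noise is well below every
tolerance being asserted.

## Interface conventions

Coefficient vectors are intercept-first throughout.  σ² is accepted as a
variance; the CLI additionally accepts `--sigma`, squared on ingestion.
Scalar convenience constructors (`EffectSpec.simple`,
`PredictorSpec.simple`, `DesignSummary.simple`) cover simple regression
without matrix inputs.  Covariance matrices must be symmetric (1e-10
tolerance) and pass a Cholesky factorization: a degenerate Σ_X would
make d ill-defined as a variance.  Analytic methods refuse non-normal
predictor families rather than silently applying normal theory.  CLI
reports are YAML whose `config` block round-trips as a config file;
display rounds to 4 decimals by default with full precision behind a
flag.
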