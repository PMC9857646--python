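# Methods

## Distributional core

The CMPB(n, θ, ν) pmf is proportional to C(n,x)^ν θ^x. All normalizers,
pmfs and transition probabilities are evaluated in the log domain:
ν·log C(n,x) uses a log-gamma log-binomial coefficient and sums are
collapsed with log-sum-exp, because C(n,x)^ν overflows or underflows
quickly for negative or large ν (C(50,25)^±30 is far outside double range
while the normalized pmf is perfectly representable). The canonical
parameter is the odds θ; the success probability α = θ/(1+θ) and the
rate-like λ = θ^{1/ν} (defined only for ν ≠ 0) are convenience accessors,
since the likelihood is written in θ.

Moments and the binomial index of dispersion (BID) are computed from the
exact length-(n+1) probability vector. The analytic power-series route
(E X = θS′/S, Var X = θS′/S + θ²(S″/S − (S′/S)²)) is implemented as
`moments_power_series` and kept as a cross-check; the two are algebraically
identical and tested to agree to 1e−10.

ν is accepted anywhere on the real line. Extreme |ν| is numerically safe
but statistically degenerate: ν → +∞ concentrates mass near n/2, ν → −∞
pushes it to the endpoints {0, n}.

### Sampling

Sampling is inverse-CDF. The CDF is built by the pmf ratio recurrence
P(x+1) = P(x) · ((n−x)/(x+1))^ν · θ starting from P(0) = 1/S, accumulating
in the probability domain (n is small, so no underflow risk beyond the
normalizer, which is log-domain), with the final CDF entry clamped to 1
against ~1e−16 rounding shortfall. A literal stepping sampler
(`sample_one`: accumulate F term by term until the uniform falls below it)
is retained and unit-tested to agree draw-for-draw with the vectorized
searchsorted path — both consume exactly one uniform per draw.

### Exchangeable counting vectors

The joint law of the n dependent Bernoulli indicators behind a CMPB count
is C(n,x)^{ν−1} θ^x / S with x the vector sum, so it depends on the vector
only through its sum (full exchangeability). `cmpb_thin_vector` realizes
the vector by drawing the total and placing the ones uniformly at random —
exact, because any allocation rule that is uniform over positions given the
total reproduces a sum-determined joint law. This makes order-2
exchangeability (equal pairwise joint laws, symmetric off-diagonal cells)
directly testable.

## The CMPBAR(1) chain

One step adds two conditionally independent CMPB thinnings (survival of the
previous count at odds θ₁, revival of its complement at odds θ₂, shared ν).
The transition probability is the convolution

P(k|l) ∝ Σ_i C(l,i)^ν C(n−l, k−i)^ν θ₁^i θ₂^{k−i},

where the index i runs over max(0, k−(n−l)) … min(k, l) only: terms outside
that range have a vanishing binomial coefficient, and 0^ν is undefined for
ν ≤ 0, so they are excluded rather than exponentiated. The full
(n+1)×(n+1) matrix is assembled in one vectorized log-sum-exp pass; its
rows are tested to sum to 1 within 1e−12 and all entries are strictly
positive, which makes the chain irreducible and aperiodic on {0,…,n}.

The stationary law solves πP = π exactly: the dense balance system with the
last equation replaced by Σπ = 1. No eigen-iteration tolerance is involved;
n in the tens to low hundreds is the intended regime. The stationary BID is
computed from this exact π (rather than estimated from simulated paths):
>1 for ν < 1, =1 at ν = 1 (where the whole model collapses to the
classical binomial AR(1) with stationary law Bin(n, β/(1−α+β))), <1 for
ν > 1.

`simulate` defaults to a stationary start (X₀ drawn from the exact π, no
burn-in); with an explicit starting state the default burn-in is 500 steps.
The generative law does not pin down X₀, and a stationary start removes
transient bias from the Monte-Carlo study. The per-state conditional CDFs
of the two thinning components are precomputed once per call, so each step
costs two searchsorted draws; this is the stepping sampler with its CDF
cached, and is tested to reproduce the literal two-thinnings-per-step path
uniform-for-uniform.

## Estimation

The conditional log-likelihood is a sum over observed transitions, so it is
computed as ⟨counts, log P⟩ with a transition-pair count matrix — one
log-matrix build per likelihood evaluation regardless of T. Optimization
runs in the unconstrained coordinates (log θ₁, log θ₂, ν) with L-BFGS-B;
the default start sets θ₁ = θ₂ from a ν = 1 moment fit (α̂ = β̂ = sample
mean / n) and ν = 1, the neutral binomial submodel. If the line search
fails, a multi-start fallback re-solves from ν ∈ {0.5, 1.5, 0} and keeps
the best optimum; non-convergence is flagged in the result, never silent.
A constant series (e.g. stuck at 0 or n) raises a non-identifiability
error. Single-series fits at T = 500 were verified against exhaustive
multi-start Nelder-Mead at tight tolerances (log-likelihood agreement to
~1e−7), so the quasi-Newton path finds the global CML optimum in this
model's practical regime.

Covariance: per-transition scores and Hessians of log P_η come from central
finite differences on the log-transition matrix in the natural (θ₁, θ₂, ν)
coordinates (relative step 1e−5, Hessian symmetrized). Two estimators are
exposed — the observed-information form (−J̄)⁻¹/T (default) and the
sandwich J̄⁻¹ Ī J̄⁻¹/T with Ī the average score outer product — because
published per-parameter standard errors for such models rarely state which
was used; under correct specification they agree asymptotically
(trace(J⁻¹I) ≈ number of parameters, which is probed in the tests). An
information matrix with condition number above 1e8 triggers a warning (the
ν direction can flatten near ν-identifiability boundaries); above 1e12 the
covariance is refused with the flat direction named.

The BAR(1) competitor is fitted with the same machinery at ν = 1, optimized
in (logit α, logit β) — a bijection onto the admissible (π, ρ) region —
and reported in the customary (π, ρ) parameterization with
observed-information SEs computed directly in those coordinates.
AIC = 2k − 2ℓ and BIC = k log T − 2ℓ use T = number of transitions
(length − 1), consistent with conditioning on X₀.

## Diagnostics

Pearson residuals standardize by the exact conditional mean and variance
(sums of the two components' power-series moments, cross-checked against
transition-row moments to 1e−10). The PIT is the non-randomized
(mean-PIT) construction for discrete data: each transition contributes a
linear ramp between the conditional CDF at Xₜ−1 and at Xₜ, averaged across
transitions and binned (default 10 bins — the customary display choice,
configurable); it is deterministic, unlike the randomized PIT.
ACF/PACF delegate to statsmodels.

## Synthetic data and the Monte-Carlo study

The simulation study reproduces the canonical design: n = 10, scenarios
(θ₁, θ₂) ∈ {(0.25,0.25), (0.25,1), (0.25,1.5), (1,1.5)} crossed with
ν ∈ {0.5, 1, 1.5} (over-, equi-, under-dispersion), T ∈ {100, 300, 500}.
The per-cell spread is reported exactly as the study defines it:
sd = √((1/(m−1)) Σ (φ̂ᵢ − φ)²) about the TRUE value — an RMSE-like
quantity, not a spread about the replication mean; the conventional
about-the-mean sd is emitted in a separate column. Per-replication RNG
streams are spawned from the master seed with counter-based spawn keys
(scenario index, T index, replication index), so a study is byte-
reproducible and independent of scheduling. Replication counts are
configurable; the packaged acceptance runs use 1,000 replications per cell,
which resolves Monte-Carlo means to ~0.002–0.007 and is a desk-scale
stand-in for the original 10,000-replication design (reproducible overnight
with `reps=10000`).

The packaged fixture is a synthetic stand-in for a six-year weekly count
calendar: n = 7, 313 observations, parameters (θ₁, θ₂, ν) =
(1.2313, 0.9547, 0.0995) in the mildly over-dispersed regime, so its sample
BID typically exceeds 1. It emulates the dispersion structure and Markov
dependence of such data, not calendar artifacts (seasonality, trend,
missing weeks) — passing fixture tests therefore demonstrates estimator
correctness under the model, not robustness to real-world
misspecification.

Known limitations: the marginal ACF has no closed form (only the exact
one-step structure is exposed; k-step laws follow from matrix powers);
estimation assumes n is known and structural, and n is never inferred from
the observed maximum; the sampling distribution of θ̂₁ is noticeably
right-skewed at T = 500 when θ₁ is small and ν > 1 (under-dispersed, low
survival odds), so normal-approximation intervals for that corner are
first-order only.
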