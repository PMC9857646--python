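# cmpbar

Bounded count time series — weekly rainy days out of 7, occupied beds out of
n, infected herds out of n — are routinely fitted with the binomial AR(1)
model, which forces equi-dispersion: its stationary law is binomial, so the
binomial index of dispersion

BID(X) = n·Var(X) / (E(X)·(n − E(X)))

is pinned at 1. Real series are often over-dispersed (BID > 1) or
under-dispersed (BID < 1), and the classical model also assumes the n units
flip states independently. `cmpbar` implements a bounded AR(1) built from
*exchangeable, dependent* counting variables that covers all three dispersion
regimes with a single extra parameter.

## The model

The Conway–Maxwell–Poisson-binomial (CMPB) distribution on {0, …, n} tilts
the binomial by a dispersion exponent ν:

P(X = x) = C(n,x)^ν · θ^x / S(θ, ν),  S(θ, ν) = Σₓ C(n,x)^ν θ^x,

with odds θ = α/(1−α) > 0 and ν ∈ ℝ. ν = 1 recovers Binomial(n, α); ν = 0
gives a truncated geometric; ν < 1 spreads mass outward (BID ≥ 1) and ν > 1
concentrates it (BID ≤ 1). The CMPB is the law of a sum of n exchangeable,
dependent Bernoulli indicators, which yields the exchangeable CMPB thinning
operator: applied to a count x it returns a CMPB(x, α, ν) draw. The CMPBAR(1)
process combines two independent thinnings per step,

Xₜ = α ◇_ν Xₜ₋₁ + β ◇_ν (n − Xₜ₋₁),

survivors of the previous count plus revivals from its complement, with
survival odds θ₁ = α/(1−α), revival odds θ₂ = β/(1−β) and shared ν. The chain
is a strictly positive finite Markov chain, hence ergodic; the package
computes its transition matrix and stationary law exactly, estimates
η = (θ₁, θ₂, ν) by conditional maximum likelihood (CML)

ℓ(η) = Σₜ log P_η(Xₜ | Xₜ₋₁),

reports Hessian or sandwich (J⁻¹IJ⁻¹) standard errors, AIC/BIC against the
binomial AR(1) competitor, and Pearson-residual and PIT diagnostics.

## Worked example

Simulate an over-dispersed weekly series (n = 7, ν ≈ 0.1) and fit both
models:

```sh
cmpbar simulate --n 7 --theta1 1.23 --theta2 0.95 --nu 0.1 --T 312 --seed 7 -o rain.txt
cmpbar fit rain.txt --n 7 -o fit.json
```

```json
{
  "estimates": {"theta1": 1.2495, "theta2": 0.9836, "nu": 0.1416},
  "se":        {"theta1": 0.0695, "theta2": 0.0625, "nu": 0.0772},
  "loglik": -605.70, "aic": 1217.40, "bic": 1228.63
}
```

All three generating parameters are recovered within one standard error.
The binomial AR(1) fit of the same series (`--model bar1`) gives
loglik −655.83, AIC 1315.66: forty AIC points worse, because it cannot
represent the extra-binomial variation (the fitted ν̂ = 0.14 is far below
the equi-dispersed value 1). Diagnostics of the CMPB fit
(`cmpbar diagnose rain.txt fit.json`) give Pearson residual mean 0.0018 and
variance 0.977, with a PIT uniformity p-value of 0.995 — a calibrated model.

The same functionality is available as a library:

```python
import numpy as np
from cmpbar import CMPBARParams, simulate, cml_fit, stationary_bid

params = CMPBARParams(n=10, theta1=0.25, theta2=0.25, nu=0.5)
stationary_bid(params)          # 1.288... -> over-dispersed regime
series = simulate(params, 500, np.random.default_rng(1))
fit = cml_fit(series)
fit.estimates, fit.se
```

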