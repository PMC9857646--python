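"""Random thinning operators for bounded-count autoregressions.

``cmpb_thin`` is the exchangeable CMPB thinning: conditional on its integer
argument x, the thinned value is a CMPB(x, alpha, nu) draw — the sum of x
dependent, exchangeable Bernoulli indicators whose joint law is the counting
distribution of the CMPB.  ``binomial_thin`` is the classical operator with
iid Bernoulli(alpha) indicators, used by the binomial AR(1) competitor.
"""

from __future__ import annotations

import numpy as np

from .distribution import CMPBSpec, sample, sample_one


def cmpb_thin(x: int, theta: float, nu: float, rng: np.random.Generator) -> int:
    """One draw of the exchangeable CMPB thinning applied to x.

    Conditional on x, the result follows CMPB(x, alpha, nu) with
    alpha = theta/(1+theta); x = 0 returns 0 deterministically.
    """
    if x < 0:
        raise ValueError(f"thinning argument must be non-negative, got {x}")
    if x == 0:
        return 0
    return int(sample_one(CMPBSpec(n=int(x), theta=theta, nu=nu), rng))


def binomial_thin(x: int, alpha: float, rng: np.random.Generator) -> int:
    """Classical binomial thinning: Binomial(x, alpha) draw; x = 0 gives 0."""
    if x < 0:
        raise ValueError(f"thinning argument must be non-negative, got {x}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha!r}")
    if x == 0:
        return 0
    return int(rng.binomial(x, alpha))


def cmpb_thin_vector(
    x: int, theta: float, nu: float, rng: np.random.Generator
) -> np.ndarray:
    """The exchangeable indicator vector behind one CMPB thinning draw.

    Draws the total from CMPB(x, alpha, nu) and places that many ones
    uniformly at random among the x slots.  Because the joint counting law
    depends on the indicators only through their sum, this realizes the
    exchangeable Bernoulli sequence exactly; it exists so that pairwise
    (order-2) exchangeability properties are directly testable.
    """
    if x < 0:
        raise ValueError(f"thinning argument must be non-negative, got {x}")
    if x == 0:
        return np.zeros(0, dtype=np.int64)
    total = int(sample(CMPBSpec(n=int(x), theta=theta, nu=nu), 1, rng)[0])
    z = np.zeros(x, dtype=np.int64)
    z[rng.choice(x, size=total, replace=False)] = 1
    return z
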