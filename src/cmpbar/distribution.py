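"""Conway-Maxwell-Poisson-binomial (CMPB) distribution.

The CMPB law on {0, ..., n} tilts the binomial by a dispersion exponent nu:

    P(X = x) = C(n, x)^nu * theta^x / S(theta, nu),
    S(theta, nu) = sum_{x=0}^{n} C(n, x)^nu * theta^x,

with odds parameter theta = alpha / (1 - alpha) > 0 and nu real.  nu = 1
recovers Binomial(n, alpha); nu = 0 gives the truncated geometric power-series
law theta^x / sum theta^x; nu < 1 produces over-dispersion relative to the
binomial and nu > 1 under-dispersion, as measured by the binomial index of
dispersion BID = n Var(X) / (E(X) (n - E(X))).

All normalizers and probabilities are evaluated in the log domain with
log-sum-exp, since C(n, x)^nu over/underflows rapidly for negative or large nu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp


def log_binom_coeffs(n: int) -> np.ndarray:
    """log C(n, x) for x = 0..n via log-gamma."""
    x = np.arange(n + 1)
    return gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)


@dataclass(frozen=True)
class CMPBSpec:
    """Parameters (n, theta, nu) of one CMPB law.

    Parameters
    ----------
    n
        Predetermined upper limit of the range (n >= 1).
    theta
        Odds parameter, theta = alpha / (1 - alpha) > 0.
    nu
        Real dispersion exponent.
    """

    n: int
    theta: float
    nu: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError(f"theta must be positive and finite, got {self.theta!r}")
        if not np.isfinite(self.nu):
            raise ValueError(f"nu must be finite, got {self.nu!r}")

    @classmethod
    def from_alpha(cls, n: int, alpha: float, nu: float) -> "CMPBSpec":
        """Construct from the success probability alpha in (0, 1)."""
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
        return cls(n=n, theta=alpha / (1.0 - alpha), nu=nu)

    @property
    def alpha(self) -> float:
        """Success probability alpha = theta / (1 + theta)."""
        return self.theta / (1.0 + self.theta)

    @property
    def lam(self) -> float:
        """Rate-like parameter lambda with theta = lambda^nu (nu != 0 only)."""
        if self.nu == 0:
            raise ValueError("lambda is defined only for nu != 0")
        return self.theta ** (1.0 / self.nu)


def log_weights(spec: CMPBSpec) -> np.ndarray:
    """Unnormalized log masses nu*log C(n,x) + x*log theta, x = 0..n."""
    x = np.arange(spec.n + 1)
    return spec.nu * log_binom_coeffs(spec.n) + x * np.log(spec.theta)


def log_normalizer(spec: CMPBSpec) -> float:
    """log S(theta, nu) = log sum_x C(n,x)^nu theta^x, by log-sum-exp."""
    return float(logsumexp(log_weights(spec)))


def log_pmf_vector(spec: CMPBSpec) -> np.ndarray:
    lw = log_weights(spec)
    return lw - logsumexp(lw)


def pmf_vector(spec: CMPBSpec) -> np.ndarray:
    """All n+1 probabilities; sums to 1 to within numerical roundoff."""
    return np.exp(log_pmf_vector(spec))


def pmf(spec: CMPBSpec, x: int) -> float:
    """P(X = x) = C(n,x)^nu theta^x / S(theta, nu)."""
    if not 0 <= x <= spec.n:
        raise ValueError(f"x must lie in {{0..{spec.n}}}, got {x}")
    return float(np.exp(log_pmf_vector(spec)[x]))


def moments(spec: CMPBSpec) -> tuple[float, float]:
    """Mean and variance, computed from the exact probability vector.

    Algebraically identical to the power-series route
    E(X) = theta S'/S, Var(X) = theta S'/S + theta^2 (S''/S - (S'/S)^2),
    which :func:`moments_power_series` keeps as a cross-check.
    """
    p = pmf_vector(spec)
    x = np.arange(spec.n + 1)
    mean = float(x @ p)
    var = float((x - mean) ** 2 @ p)
    return mean, var


def moments_power_series(spec: CMPBSpec) -> tuple[float, float]:
    """Mean and variance via termwise derivatives of S(theta, nu) in theta."""
    x = np.arange(spec.n + 1)
    lw = log_weights(spec)  # log of C(n,x)^nu theta^x
    log_s = logsumexp(lw)
    # theta S' = sum x * w_x ; theta^2 S'' = sum x (x-1) w_x
    with np.errstate(divide="ignore"):
        log_ts1 = logsumexp(lw, b=x)
        log_ts2 = logsumexp(lw, b=x * (x - 1.0))
    r1 = np.exp(log_ts1 - log_s)  # theta S'/S
    r2 = np.exp(log_ts2 - log_s)  # theta^2 S''/S
    mean = float(r1)
    var = float(r1 + r2 - r1**2)
    return mean, var


def bid(spec: CMPBSpec) -> float:
    """Binomial index of dispersion n Var(X) / (E(X) (n - E(X))).

    Equals 1 for nu = 1 (binomial), exceeds 1 for nu < 1 (over-dispersion)
    and falls below 1 for nu > 1 (under-dispersion).
    """
    mean, var = moments(spec)
    return spec.n * var / (mean * (spec.n - mean))


def _cdf(spec: CMPBSpec) -> np.ndarray:
    """CDF built by the pmf ratio recurrence p_{x+1} = p_x ((n-x)/(x+1))^nu theta.

    This is the accumulation loop of the inverse-CDF sampling algorithm:
    start from p_0 = 1/S, multiply by the one-step ratio, accumulate F.
    Probability-domain accumulation is safe because n is small; the final
    entry is clamped to 1 against ~1e-16 rounding shortfall.
    """
    n = spec.n
    p = np.empty(n + 1)
    p[0] = np.exp(-log_normalizer(spec))
    x = np.arange(n)
    ratios = ((n - x) / (x + 1.0)) ** spec.nu * spec.theta
    for i in range(n):
        p[i + 1] = p[i] * ratios[i]
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    return cdf


def sample(spec: CMPBSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw iid CMPB variates by inverse CDF.

    For each uniform u the returned value is the first x with u < F(x),
    F built by the ratio recurrence; vectorized via searchsorted on the
    shared CDF.
    """
    cdf = _cdf(spec)
    u = rng.random(size)
    return np.searchsorted(cdf, u, side="right").astype(np.int64)


def sample_one(spec: CMPBSpec, rng: np.random.Generator) -> int:
    """Single draw by the literal stepping loop (kept as sampling oracle).

    Step p <- p * ((n-x)/(x+1))^nu * theta, F <- F + p, until u < F;
    terminates in at most n+1 steps since F reaches 1.
    """
    u = rng.random()
    x = 0
    p = np.exp(-log_normalizer(spec))
    f = p
    while u >= f and x < spec.n:
        p = p * ((spec.n - x) / (x + 1.0)) ** spec.nu * spec.theta
        f = f + p
        x += 1
    return x


def joint_counting_pmf(spec: CMPBSpec, z) -> float:
    """Probability of one binary counting vector (z_1, ..., z_n).

    The exchangeable Bernoulli sequence underlying the CMPB law has
    P(Z_1=z_1, ..., Z_n=z_n) = C(n, x)^{nu-1} theta^x / S(theta, nu) with
    x = sum z_i; the value depends on z only through its sum, so every
    permutation of z has the same probability.
    """
    z = np.asarray(z)
    if z.shape != (spec.n,):
        raise ValueError(f"z must be a binary vector of length {spec.n}")
    if not np.isin(z, (0, 1)).all():
        raise ValueError("z must contain only 0/1 entries")
    x = int(z.sum())
    lbc = log_binom_coeffs(spec.n)
    log_p = (spec.nu - 1.0) * lbc[x] + x * np.log(spec.theta) - log_normalizer(spec)
    return float(np.exp(log_p))
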