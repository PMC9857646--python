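"""The CMPBAR(1) bounded-count autoregression.

The model evolves a count on {0, ..., n} by two independent exchangeable
CMPB thinnings per step:

    X_t = survival_thin(X_{t-1}; theta1, nu) + revival_thin(n - X_{t-1}; theta2, nu)

i.e. of the X_{t-1} units active at t-1 a CMPB(X_{t-1}, alpha, nu)-distributed
number survive, and of the n - X_{t-1} inactive units a
CMPB(n - X_{t-1}, beta, nu)-distributed number revive, with survival odds
theta1 = alpha/(1-alpha) and revival odds theta2 = beta/(1-beta) and a shared
dispersion exponent nu.  The chain is a finite, irreducible, aperiodic Markov
chain (every one-step transition probability is strictly positive), hence
ergodic with a unique stationary law, which this module computes exactly by a
dense linear solve.  nu = 1 collapses the model to the classical binomial
AR(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

from .distribution import CMPBSpec, _cdf, moments


@dataclass(frozen=True)
class CMPBARParams:
    """CMPBAR(1) parameter vector eta = (theta1, theta2, nu) with fixed range n."""

    n: int
    theta1: float
    theta2: float
    nu: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        for name in ("theta1", "theta2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if not np.isfinite(self.nu):
            raise ValueError(f"nu must be finite, got {self.nu!r}")

    @classmethod
    def from_probs(cls, n: int, alpha: float, beta: float, nu: float) -> "CMPBARParams":
        """Construct from survival/revival probabilities alpha, beta in (0,1)."""
        if not (0 < alpha < 1 and 0 < beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        return cls(n=n, theta1=alpha / (1 - alpha), theta2=beta / (1 - beta), nu=nu)

    @property
    def alpha(self) -> float:
        return self.theta1 / (1.0 + self.theta1)

    @property
    def beta(self) -> float:
        return self.theta2 / (1.0 + self.theta2)

    @property
    def eta(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.nu])


@dataclass(frozen=True)
class CountSeries:
    """A validated integer series on {0..n} with its known range limit n."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-d array")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(v == np.floor(v)):
                raise ValueError("series values must be integers")
            v = v.astype(np.int64)
        if v.min() < 0 or v.max() > self.n:
            bad = np.flatnonzero((v < 0) | (v > self.n))
            raise ValueError(
                f"values outside {{0..{self.n}}} at positions {bad[:10].tolist()}"
            )
        object.__setattr__(self, "values", v.astype(np.int64))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_transitions(self) -> int:
        return len(self.values) - 1

    def transition_counts(self) -> np.ndarray:
        """(n+1) x (n+1) matrix of observed one-step transition counts."""
        c = np.zeros((self.n + 1, self.n + 1), dtype=np.int64)
        np.add.at(c, (self.values[:-1], self.values[1:]), 1)
        return c


@lru_cache(maxsize=32)
def _binom_tables(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(log C(m, i) table, validity mask) for m, i = 0..n; invalid cells 0/False."""
    m = np.arange(n + 1)[:, None]
    i = np.arange(n + 1)[None, :]
    valid = i <= m
    lbc = np.where(
        valid, gammaln(m + 1) - gammaln(i + 1) - gammaln(np.where(valid, m - i, 0) + 1), 0.0
    )
    return lbc, valid


def log_transition_matrix(params: CMPBARParams) -> np.ndarray:
    """(n+1) x (n+1) matrix of log P(X_t = k | X_{t-1} = l).

    Row l is the convolution of CMPB(l, theta1, nu) with CMPB(n-l, theta2, nu):

        P(k|l) = sum_i C(l,i)^nu C(n-l,k-i)^nu theta1^i theta2^{k-i}
                 / (S(theta1,nu; l) S(theta2,nu; n-l)),

    the sum restricted to max(0, k-(n-l)) <= i <= min(k, l); terms whose
    binomial coefficient vanishes are excluded rather than exponentiated
    (0^nu is undefined for nu <= 0).  Each term is evaluated in the log
    domain with a final log-sum-exp.
    """
    n = params.n
    lbc, valid = _binom_tables(n)
    i = np.arange(n + 1)
    lt1, lt2 = np.log(params.theta1), np.log(params.theta2)
    # A[l, i]: log of C(l, i)^nu theta1^i ; B[l, j]: log of C(n-l, j)^nu theta2^j
    A = np.where(valid, params.nu * lbc + i * lt1, -np.inf)
    B = np.where(valid, params.nu * lbc + i * lt2, -np.inf)[::-1]
    with np.errstate(invalid="ignore"):
        log_s1 = logsumexp(A, axis=1)
        log_s2 = logsumexp(B, axis=1)
        # terms[l, k, i] = A[l, i] + B[l, k - i]
        j = i[:, None] - i[None, :]  # (k, i)
        ok = (j >= 0) & (j <= n)
        jc = np.clip(j, 0, n)
        terms = A[:, None, :] + np.where(ok[None], B[:, jc], -np.inf)
        log_p = logsumexp(terms, axis=2) - log_s1[:, None] - log_s2[:, None]
    return log_p


def transition_matrix(params: CMPBARParams) -> np.ndarray:
    """Row-stochastic one-step transition matrix; every entry is positive."""
    return np.exp(log_transition_matrix(params))


def transition_probability(params: CMPBARParams, k: int, l: int) -> float:
    """P(X_t = k | X_{t-1} = l)."""
    n = params.n
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in {{0..{n}}}, got {k}")
    if not 0 <= l <= n:
        raise ValueError(f"l must lie in {{0..{n}}}, got {l}")
    return float(transition_matrix(params)[l, k])


def stationary_distribution(params: CMPBARParams) -> np.ndarray:
    """The unique stationary law pi with pi P = pi, solved as a dense linear system.

    The last balance equation is replaced by the normalization constraint
    sum(pi) = 1; exact for the small state spaces this model lives on.
    """
    p = transition_matrix(params)
    n1 = params.n + 1
    a = p.T - np.eye(n1)
    a[-1, :] = 1.0
    b = np.zeros(n1)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def _component_cdfs(params: CMPBARParams) -> tuple[list, list]:
    """Conditional CDFs of the two thinning components for every previous state."""
    surv = [None] + [
        _cdf(CMPBSpec(n=l, theta=params.theta1, nu=params.nu))
        for l in range(1, params.n + 1)
    ]
    rev = [
        _cdf(CMPBSpec(n=params.n - l, theta=params.theta2, nu=params.nu))
        if l < params.n
        else None
        for l in range(params.n + 1)
    ]
    return surv, rev


def simulate(
    params: CMPBARParams,
    T: int,
    rng: np.random.Generator,
    x0: int | str = "stationary",
    burnin: int | None = None,
) -> CountSeries:
    """Generate a CMPBAR(1) path of length T+1 (X_0, ..., X_T).

    Each step draws the two thinnings independently by inverse CDF; the
    per-state conditional CDFs are precomputed once, which reproduces the
    literal per-draw stepping sampler uniform-for-uniform.  ``x0`` is either
    an explicit starting state or ``"stationary"`` (the default), which draws
    X_0 from the exact stationary law; with an explicit start the default
    burn-in is 500 steps, with a stationary start none is needed.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    n = params.n
    if x0 == "stationary":
        if burnin is None:
            burnin = 0
        pi = stationary_distribution(params)
        x = int(rng.choice(n + 1, p=pi))
    else:
        x = int(x0)
        if not 0 <= x <= n:
            raise ValueError(f"x0 must lie in {{0..{n}}}, got {x0}")
        if burnin is None:
            burnin = 500
    surv, rev = _component_cdfs(params)
    search = np.searchsorted
    out = np.empty(T + 1, dtype=np.int64)
    for t in range(-burnin, T + 1):
        if t >= 0:
            out[t] = x
        if t == T:
            break
        s = int(search(surv[x], rng.random(), side="right")) if x > 0 else 0
        r = int(search(rev[x], rng.random(), side="right")) if x < n else 0
        x = s + r
    return CountSeries(values=out, n=n)


def conditional_moments(params: CMPBARParams, l: int) -> tuple[float, float]:
    """Mean and variance of X_t given X_{t-1} = l.

    The two thinning components are conditionally independent, so the
    moments are the sums of the CMPB(l, theta1, nu) and CMPB(n-l, theta2, nu)
    component moments (a component on an empty range contributes zero).
    """
    if not 0 <= l <= params.n:
        raise ValueError(f"l must lie in {{0..{params.n}}}, got {l}")
    mean = var = 0.0
    if l > 0:
        m1, v1 = moments(CMPBSpec(n=l, theta=params.theta1, nu=params.nu))
        mean += m1
        var += v1
    if l < params.n:
        m2, v2 = moments(CMPBSpec(n=params.n - l, theta=params.theta2, nu=params.nu))
        mean += m2
        var += v2
    return mean, var


def cbid(params: CMPBARParams, l: int) -> float:
    """Conditional binomial index of dispersion of X_t | X_{t-1} = l."""
    mean, var = conditional_moments(params, l)
    return params.n * var / (mean * (params.n - mean))


def stationary_bid(params: CMPBARParams) -> float:
    """BID of the exact stationary law: n Var / (E (n - E)) under pi.

    Greater than 1 for nu < 1 (over-dispersion), 1 at nu = 1, below 1 for
    nu > 1.
    """
    pi = stationary_distribution(params)
    x = np.arange(params.n + 1)
    mean = float(x @ pi)
    var = float((x - mean) ** 2 @ pi)
    return params.n * var / (mean * (params.n - mean))
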