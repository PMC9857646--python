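"""Conditional maximum likelihood (CML) inference for CMPBAR(1) and BAR(1).

Estimation conditions on the first observation and maximizes

    l(eta) = sum_{t=1}^{T} log P_eta(X_t | X_{t-1}),

the sum of log one-step transition probabilities, over eta = (theta1,
theta2, nu).  The search runs in the unconstrained coordinates (log theta1,
log theta2, nu) by quasi-Newton (L-BFGS-B) with a multi-start fallback.

Asymptotic covariance follows the sandwich form J^{-1} I J^{-1} / T, with I
the average outer product of per-transition scores and J the average
per-transition Hessian of the log transition probability, both obtained by
central finite differences on the log-transition matrix; the Hessian-only
estimator (-J)^{-1} / T (the two coincide in expectation under correct
specification) is the default reported standard error.

The binomial AR(1) competitor is fitted in its customary (pi, rho)
parameterization — stationary mean fraction pi and autocorrelation rho, with
survival probability alpha = beta + rho and revival probability
beta = (1 - rho) pi — whose transition law is the nu = 1 special case of the
CMPBAR machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .process import CMPBARParams, CountSeries, log_transition_matrix


@dataclass(frozen=True)
class FitResult:
    """Outcome of one conditional-ML fit."""

    model: str  # "cmpbar" | "bar1"
    n: int
    estimates: dict[str, float]
    se: dict[str, float]
    covariance: np.ndarray
    loglik: float
    aic: float
    bic: float
    n_transitions: int
    converged: bool
    iterations: int
    init: np.ndarray
    se_method: str = "hessian"

    @property
    def params(self) -> CMPBARParams:
        """The fitted CMPBAR parameters (BAR(1) maps to nu = 1)."""
        if self.model == "cmpbar":
            return CMPBARParams(
                n=self.n,
                theta1=self.estimates["theta1"],
                theta2=self.estimates["theta2"],
                nu=self.estimates["nu"],
            )
        pi_, rho = self.estimates["pi"], self.estimates["rho"]
        alpha = rho + (1 - rho) * pi_
        beta = (1 - rho) * pi_
        return CMPBARParams.from_probs(self.n, alpha, beta, 1.0)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n": self.n,
            "estimates": self.estimates,
            "se": self.se,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "T": self.n_transitions,
            "converged": self.converged,
            "iterations": self.iterations,
            "se_method": self.se_method,
        }


def information_criteria(loglik: float, k: int, T: int) -> tuple[float, float]:
    """AIC = 2k - 2 loglik and BIC = k log(T) - 2 loglik."""
    if T < 1 or k < 0:
        raise ValueError("need T >= 1 and k >= 0")
    aic = 2 * k - 2 * loglik
    bic = (k * np.log(T) if k else 0.0) - 2 * loglik
    return float(aic), float(bic)


def conditional_loglik(params: CMPBARParams, series: CountSeries) -> float:
    """l(eta) = sum_t log P_eta(X_t | X_{t-1}), conditioning on X_0."""
    if series.n != params.n:
        raise ValueError("series range limit does not match model n")
    if len(series) < 2:
        raise ValueError("need a series of length >= 2")
    counts = series.transition_counts()
    return float((counts * log_transition_matrix(params)).sum())


def _counts_loglik(counts: np.ndarray, n: int, theta1, theta2, nu) -> float:
    params = CMPBARParams(n=n, theta1=float(theta1), theta2=float(theta2), nu=float(nu))
    return float((counts * log_transition_matrix(params)).sum())


def _validate_for_fit(series: CountSeries) -> None:
    if len(series) < 2:
        raise ValueError("need a series of length >= 2 to fit")
    v = series.values
    if v.min() == v.max():
        raise ValueError(
            "series is constant; transition parameters are not identifiable"
        )


def _default_init(series: CountSeries) -> np.ndarray:
    """Moment start: alpha = beta = sample mean / n under the nu=1 submodel."""
    a = float(np.clip(series.values.mean() / series.n, 0.05, 0.95))
    lt = np.log(a / (1 - a))
    return np.array([lt, lt, 1.0])


def cml_fit(
    series: CountSeries,
    init: np.ndarray | None = None,
    se_method: str = "hessian",
) -> FitResult:
    """Fit the CMPBAR(1) model by conditional maximum likelihood.

    Parameters
    ----------
    series
        Observed counts on {0..n} with known n.
    init
        Optional starting vector (theta1, theta2, nu); by default theta1 and
        theta2 come from a nu = 1 moment fit of the sample mean and nu starts
        at the neutral binomial value 1.
    se_method
        "hessian" (default), "sandwich", or "none" to skip covariance work.
    """
    _validate_for_fit(series)
    counts = series.transition_counts()
    n = series.n
    if init is not None:
        z0 = np.array([np.log(init[0]), np.log(init[1]), init[2]], dtype=float)
    else:
        z0 = _default_init(series)

    def neg(z):
        return -_counts_loglik(counts, n, np.exp(z[0]), np.exp(z[1]), z[2])

    def solve(z_start):
        return minimize(neg, z_start, method="L-BFGS-B", options={"maxiter": 200})

    res = solve(z0)
    iterations = res.nit
    if not res.success:
        # multi-start fallback across the dispersion regimes
        best = res
        for dnu in (0.5, 1.5, 0.0):
            alt = solve(np.array([z0[0], z0[1], dnu]))
            iterations += alt.nit
            if alt.fun < best.fun - 1e-10:
                best = alt
        res = best
    converged = bool(res.success)
    z = res.x
    eta = np.array([np.exp(z[0]), np.exp(z[1]), z[2]])
    params = CMPBARParams(n=n, theta1=eta[0], theta2=eta[1], nu=eta[2])
    loglik = -res.fun
    T = series.n_transitions
    aic, bic = information_criteria(loglik, 3, T)

    if se_method == "none":
        cov = np.full((3, 3), np.nan)
    elif se_method == "sandwich":
        cov = sandwich_covariance(series, params)
    elif se_method == "hessian":
        cov = hessian_covariance(series, params)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    names = ("theta1", "theta2", "nu")
    return FitResult(
        model="cmpbar",
        n=n,
        estimates=dict(zip(names, eta.tolist())),
        se=dict(zip(names, se.tolist())),
        covariance=cov,
        loglik=loglik,
        aic=aic,
        bic=bic,
        n_transitions=T,
        converged=converged,
        iterations=int(iterations),
        init=np.array([np.exp(z0[0]), np.exp(z0[1]), z0[2]]),
        se_method=se_method,
    )


def _fd_information(series: CountSeries, params: CMPBARParams):
    """(I_hat, J_hat): average score outer product and average Hessian.

    Central finite differences of the log-transition matrix in the natural
    (theta1, theta2, nu) coordinates, relative step 1e-5 per coordinate;
    per-transition quantities are aggregated through the transition-pair
    counts, and the Hessian is symmetrized.
    """
    counts = series.transition_counts()
    T = counts.sum()
    eta = params.eta
    h = 1e-5 * np.maximum(np.abs(eta), 1.0)

    def lmat(e):
        return log_transition_matrix(
            CMPBARParams(n=params.n, theta1=e[0], theta2=e[1], nu=e[2])
        )

    base = lmat(eta)
    plus, minus = [], []
    for i in range(3):
        ei = np.zeros(3)
        ei[i] = h[i]
        plus.append(lmat(eta + ei))
        minus.append(lmat(eta - ei))
    grad = [(plus[i] - minus[i]) / (2 * h[i]) for i in range(3)]

    hess = np.empty((3, 3), dtype=object)
    for i in range(3):
        hess[i, i] = (plus[i] - 2 * base + minus[i]) / h[i] ** 2
    for i in range(3):
        for j in range(i + 1, 3):
            ei = np.zeros(3)
            ej = np.zeros(3)
            ei[i] = h[i]
            ej[j] = h[j]
            hij = (lmat(eta + ei + ej) - lmat(eta + ei - ej)
                   - lmat(eta - ei + ej) + lmat(eta - ei - ej)) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = hij

    I_hat = np.empty((3, 3))
    J_hat = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            I_hat[i, j] = (counts * grad[i] * grad[j]).sum() / T
            J_hat[i, j] = (counts * hess[i, j]).sum() / T
    I_hat = (I_hat + I_hat.T) / 2
    J_hat = (J_hat + J_hat.T) / 2
    return I_hat, J_hat, int(T)


def _safe_inv(J: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > 1e12:
        flat = np.linalg.eigh(J)[1][:, np.argmin(np.abs(np.linalg.eigvalsh(J)))]
        raise np.linalg.LinAlgError(
            f"information matrix is singular; flat direction ~ {flat.round(3)}"
        )
    if cond > 1e8:
        warnings.warn(
            f"information matrix is ill-conditioned (cond={cond:.2e}); "
            "standard errors may be unreliable",
            RuntimeWarning,
        )
    return np.linalg.inv(J)


def sandwich_covariance(series: CountSeries, params: CMPBARParams) -> np.ndarray:
    """Sandwich covariance J^{-1} I J^{-1} / T of the CML estimator."""
    I_hat, J_hat, T = _fd_information(series, params)
    Jinv = _safe_inv(J_hat)
    cov = Jinv @ I_hat @ Jinv / T
    return (cov + cov.T) / 2


def hessian_covariance(series: CountSeries, params: CMPBARParams) -> np.ndarray:
    """Observed-information covariance (-J)^{-1} / T."""
    _, J_hat, T = _fd_information(series, params)
    cov = _safe_inv(-J_hat) / T
    return (cov + cov.T) / 2


def bar1_fit(series: CountSeries, se_method: str = "hessian") -> FitResult:
    """CML fit of the binomial AR(1) model, reported as (pi, rho).

    The transition law is the Binomial(l, alpha) * Binomial(n-l, beta)
    convolution, i.e. the nu = 1 CMPBAR transition; the optimization runs in
    (logit alpha, logit beta), which parameterizes exactly the admissible
    (pi, rho) region.
    """
    _validate_for_fit(series)
    counts = series.transition_counts()
    n = series.n

    def neg_ab(z):
        a, b = expit(z)
        t1, t2 = a / (1 - a), b / (1 - b)
        return -_counts_loglik(counts, n, t1, t2, 1.0)

    a0 = float(np.clip(series.values.mean() / n, 0.05, 0.95))
    z0 = np.array([logit(a0), logit(a0)])
    res = minimize(neg_ab, z0, method="L-BFGS-B", options={"maxiter": 200})
    a, b = expit(res.x)
    pi_hat = b / (1 - a + b)
    rho_hat = a - b
    loglik = -res.fun
    T = series.n_transitions
    aic, bic = information_criteria(loglik, 2, T)

    if se_method == "none":
        cov = np.full((2, 2), np.nan)
    else:
        cov = _bar1_covariance(counts, n, pi_hat, rho_hat, T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    names = ("pi", "rho")
    return FitResult(
        model="bar1",
        n=n,
        estimates=dict(zip(names, [float(pi_hat), float(rho_hat)])),
        se=dict(zip(names, se.tolist())),
        covariance=cov,
        loglik=loglik,
        aic=aic,
        bic=bic,
        n_transitions=T,
        converged=bool(res.success),
        iterations=int(res.nit),
        init=np.array([a0, 0.0]),
        se_method=se_method,
    )


def _bar1_covariance(counts, n, pi_hat, rho_hat, T) -> np.ndarray:
    """Observed-information covariance in the (pi, rho) coordinates."""

    def ll(pi_, rho):
        a = rho + (1 - rho) * pi_
        b = (1 - rho) * pi_
        return _counts_loglik(counts, n, a / (1 - a), b / (1 - b), 1.0)

    x = np.array([pi_hat, rho_hat])
    h = 1e-5 * np.maximum(np.abs(x), 1.0)
    H = np.empty((2, 2))
    f0 = ll(*x)
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h[i]
        H[i, i] = (ll(*(x + ei)) - 2 * f0 + ll(*(x - ei))) / h[i] ** 2
    e0 = np.array([h[0], 0.0])
    e1 = np.array([0.0, h[1]])
    H[0, 1] = H[1, 0] = (
        ll(*(x + e0 + e1)) - ll(*(x + e0 - e1)) - ll(*(x - e0 + e1)) + ll(*(x - e0 - e1))
    ) / (4 * h[0] * h[1])
    cov = _safe_inv(-H)
    return (cov + cov.T) / 2
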