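"""Model-adequacy diagnostics for fitted bounded-count autoregressions.

Pearson residuals standardize each observation by its one-step conditional
mean and standard deviation; under a correctly specified model they are
approximately white with mean 0 and variance 1.  The PIT histogram uses the
non-randomized (mean) probability integral transform for discrete data: a
calibrated model yields a near-uniform histogram.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf, pacf as _sm_pacf

from .process import CMPBARParams, CountSeries, conditional_moments, transition_matrix


def pearson_residuals(series: CountSeries, params: CMPBARParams) -> np.ndarray:
    """r_t = (X_t - E[X_t|X_{t-1}]) / sd(X_t|X_{t-1}), t = 1..T."""
    if series.n != params.n:
        raise ValueError("series range limit does not match model n")
    mom = np.array([conditional_moments(params, l) for l in range(params.n + 1)])
    prev = series.values[:-1]
    curr = series.values[1:]
    mean = mom[prev, 0]
    sd = np.sqrt(mom[prev, 1])
    return (curr - mean) / sd


def pit_histogram(
    series: CountSeries, params: CMPBARParams, n_bins: int = 10
) -> np.ndarray:
    """Non-randomized PIT bin masses on [0, 1].

    For each transition the conditional CDF pair (F(x_t - 1 | l), F(x_t | l))
    spreads a unit of mass linearly over that CDF interval; bin masses average
    these ramps across transitions and sum to 1.  Uniformity indicates a
    calibrated one-step predictive distribution.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = transition_matrix(params)
    cdf = np.cumsum(p, axis=1)
    prev = series.values[:-1]
    curr = series.values[1:]
    upper = cdf[prev, curr]
    lower = np.where(curr > 0, cdf[prev, np.maximum(curr - 1, 0)], 0.0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # mean PIT cdf evaluated at the bin edges
    width = np.maximum(upper - lower, 1e-300)
    ramp = (edges[:, None] - lower[None, :]) / width[None, :]
    F_edges = np.clip(ramp, 0.0, 1.0).mean(axis=1)
    return np.diff(F_edges)


def pit_uniformity_test(bin_masses: np.ndarray, T: int) -> tuple[float, float]:
    """Chi-square test of the PIT histogram against uniformity.

    Treats T * mass as approximate bin counts; returns (statistic, p-value).
    """
    k = len(bin_masses)
    observed = bin_masses * T
    expected = T / k
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, k - 1))


def acf(series: CountSeries | np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag."""
    x = series.values if isinstance(series, CountSeries) else np.asarray(series)
    if max_lag >= len(x):
        raise ValueError("max_lag must be smaller than the series length")
    return _sm_acf(x, nlags=max_lag, fft=True)


def pacf(series: CountSeries | np.ndarray, max_lag: int) -> np.ndarray:
    """Sample partial autocorrelation at lags 0..max_lag."""
    x = series.values if isinstance(series, CountSeries) else np.asarray(series)
    if max_lag >= len(x) // 2:
        raise ValueError("max_lag must be smaller than half the series length")
    return _sm_pacf(x, nlags=max_lag, method="ywm")


def diagnostic_report(
    series: CountSeries, params: CMPBARParams, n_bins: int = 10, max_lag: int = 10
) -> dict:
    """Bundle of residual and PIT summaries, JSON-serializable."""
    r = pearson_residuals(series, params)
    masses = pit_histogram(series, params, n_bins)
    stat, pval = pit_uniformity_test(masses, len(r))
    return {
        "residual_mean": float(r.mean()),
        "residual_variance": float(r.var(ddof=1)),
        "residual_acf": acf(r, max_lag).tolist(),
        "pit_bin_masses": masses.tolist(),
        "pit_chi2": stat,
        "pit_pvalue": pval,
        "n_transitions": len(r),
    }
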