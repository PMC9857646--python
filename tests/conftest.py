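import numpy as np
import pytest

from cmpbar import CMPBARParams, SCENARIOS, SimStudyConfig, run_sim_study


@pytest.fixture
def rng():
    return np.random.default_rng(20230107)


def chi_square_gof(draws, probs, min_expected=5.0):
    """Chi-square GOF p-value of integer draws against exact cell probabilities.

    Cells with small expected counts are pooled into their neighbour so the
    chi-square approximation holds.
    """
    from scipy import stats

    n_cells = len(probs)
    observed = np.bincount(draws, minlength=n_cells).astype(float)
    expected = probs * len(draws)
    obs_p, exp_p = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_p.append(acc_o)
            exp_p.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        obs_p[-1] += acc_o
        exp_p[-1] += acc_e
    obs_p = np.array(obs_p)
    exp_p = np.array(exp_p) * obs_p.sum() / np.sum(exp_p)
    stat = ((obs_p - exp_p) ** 2 / exp_p).sum()
    return float(stats.chi2.sf(stat, len(obs_p) - 1))


@pytest.fixture(scope="session")
def replication_study():
    """Shared Monte-Carlo run over the three dispersion regimes.

    1000 replications per cell at T in {100, 500} for the over-dispersed
    (A1), equi-dispersed (B1) and under-dispersed (C1, C4) scenarios;
    reused by the estimator-consistency and asymptotic-normality checks.
    """
    config = SimStudyConfig(
        scenarios={k: SCENARIOS[k] for k in ("A1", "B1", "C1", "C4")},
        n=10,
        T_list=(100, 500),
        reps=1000,
        seed=20230107,
    )
    return run_sim_study(config)
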