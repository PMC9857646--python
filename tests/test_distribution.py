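"""Exact-value, oracle and property tests for the CMPB distribution."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cmpbar.distribution import (
    CMPBSpec,
    bid,
    joint_counting_pmf,
    log_normalizer,
    moments,
    moments_power_series,
    pmf,
    pmf_vector,
    sample,
    sample_one,
)

from conftest import chi_square_gof


def brute_log_normalizer(n, theta, nu):
    """Independent oracle: term-by-term sum at full float precision."""
    return math.log(sum(math.comb(n, x) ** nu * theta**x for x in range(n + 1)))


def brute_pmf_vector(n, theta, nu):
    w = np.array([math.comb(n, x) ** nu * theta**x for x in range(n + 1)])
    return w / w.sum()


class TestNormalizer:
    @pytest.mark.parametrize(
        "n,theta,nu,expected",
        [
            (2, 1.0, 1.0, math.log(4)),  # S = 1 + 2 + 1
            (2, 2.0, 0.0, math.log(7)),  # S = 1 + 2 + 4
            (7, 0.25, -2.0, brute_log_normalizer(7, 0.25, -2.0)),
        ],
    )
    def test_known_values(self, n, theta, nu, expected):
        assert log_normalizer(CMPBSpec(n, theta, nu)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_log_domain_survives_extreme_nu(self):
        # C(50, 25)^(-30) underflows in linear space; log route stays finite
        assert np.isfinite(log_normalizer(CMPBSpec(50, 1.0, -30.0)))
        assert np.isfinite(log_normalizer(CMPBSpec(50, 1e-8, 40.0)))


class TestPmf:
    @pytest.mark.parametrize(
        "spec,x,expected",
        [
            (CMPBSpec(2, 1.0, 1.0), 1, 0.5),  # Binomial(2, 1/2)
            (CMPBSpec(2, 2.0, 0.0), 2, 4 / 7),  # power-series special case
        ],
    )
    def test_special_cases(self, spec, x, expected):
        assert pmf(spec, x) == pytest.approx(expected, abs=1e-14)

    def test_matches_joint_enumeration(self):
        # marginalizing the exchangeable joint law over all 2^7 binary
        # vectors with sum 3 must reproduce the pmf at x = 3
        spec = CMPBSpec(7, 1.5, 0.5)
        total = sum(
            joint_counting_pmf(spec, z)
            for z in itertools.product((0, 1), repeat=7)
            if sum(z) == 3
        )
        assert pmf(spec, 3) == pytest.approx(total, abs=1e-14)

    def test_out_of_range_x_rejected(self):
        with pytest.raises(ValueError):
            pmf(CMPBSpec(5, 1.0, 1.0), 6)
        with pytest.raises(ValueError):
            pmf(CMPBSpec(5, 1.0, 1.0), -1)

    @pytest.mark.parametrize("n", [1, 5, 20])
    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("nu", [-2.0, 0.0, 1.0, 2.0])
    def test_normalization_grid(self, n, theta, nu):
        p = pmf_vector(CMPBSpec(n, theta, nu))
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()

    @pytest.mark.parametrize("theta", [0.3, 1.0, 4.0])
    def test_binomial_reduction_at_nu_one(self, theta):
        n = 9
        p = pmf_vector(CMPBSpec(n, theta, 1.0))
        ref = stats.binom.pmf(np.arange(n + 1), n, theta / (1 + theta))
        assert np.abs(p - ref).max() < 1e-12

    def test_truncated_geometric_at_nu_zero(self):
        n, theta = 6, 1.7
        p = pmf_vector(CMPBSpec(n, theta, 0.0))
        ref = theta ** np.arange(n + 1)
        ref = ref / ref.sum()
        assert np.abs(p - ref).max() < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        n=st.integers(1, 15),
        theta=st.floats(0.05, 20.0),
        nu=st.floats(-3.0, 3.0),
    )
    def test_pmf_agrees_with_brute_force(self, n, theta, nu):
        p = pmf_vector(CMPBSpec(n, theta, nu))
        ref = brute_pmf_vector(n, theta, nu)
        assert np.abs(p - ref).max() < 1e-10


class TestMoments:
    def test_binomial_case(self):
        mean, var = moments(CMPBSpec(4, 1.0, 1.0))
        assert mean == pytest.approx(2.0, abs=1e-12)
        assert var == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("nu", [-1.0, 0.0, 2.5])
    def test_bernoulli_ignores_nu(self, nu):
        theta = 0.8
        mean, var = moments(CMPBSpec(1, theta, nu))
        a = theta / (1 + theta)
        assert mean == pytest.approx(a, abs=1e-12)
        assert var == pytest.approx(a * (1 - a), abs=1e-12)

    def test_brute_force_oracle(self):
        spec = CMPBSpec(7, 0.25, -0.5)
        ref = brute_pmf_vector(7, 0.25, -0.5)
        x = np.arange(8)
        mean, var = moments(spec)
        assert mean == pytest.approx(float(x @ ref), abs=1e-12)
        assert var == pytest.approx(float((x - x @ ref) ** 2 @ ref), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        n=st.integers(1, 15),
        theta=st.floats(0.05, 10.0),
        nu=st.floats(-2.0, 2.5),
    )
    def test_power_series_route_agrees(self, n, theta, nu):
        # analytic theta S'/S route vs the probability-vector route
        spec = CMPBSpec(n, theta, nu)
        m1, v1 = moments(spec)
        m2, v2 = moments_power_series(spec)
        assert m1 == pytest.approx(m2, abs=1e-10)
        assert v1 == pytest.approx(v2, abs=1e-10)


class TestBid:
    @pytest.mark.parametrize("theta", [0.2, 1.0, 5.0])
    @pytest.mark.parametrize("n", [1, 7])
    def test_equidispersion_at_nu_one(self, n, theta):
        assert bid(CMPBSpec(n, theta, 1.0)) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("alpha", np.round(np.arange(0.1, 0.95, 0.1), 2))
    def test_dispersion_regimes(self, alpha):
        # nu below 1 inflates the BID above 1, nu above 1 deflates it
        assert bid(CMPBSpec.from_alpha(7, alpha, 0.5)) >= 1.0 - 1e-10
        assert bid(CMPBSpec.from_alpha(7, alpha, 1.0)) == pytest.approx(1.0, abs=1e-10)
        assert bid(CMPBSpec.from_alpha(7, alpha, 2.0)) <= 1.0 + 1e-10


class TestSampler:
    def test_mass_concentrates_at_zero_for_tiny_theta(self, rng):
        draws = sample(CMPBSpec(7, 1e-12, 0.5), 1000, rng)
        assert (draws == 0).all()

    @pytest.mark.parametrize(
        "theta,nu",
        [(1.0, 1.0), (1.5, -1.0), (0.25, 0.5)],
    )
    def test_gof_against_exact_pmf(self, theta, nu, rng):
        spec = CMPBSpec(7, theta, nu)
        draws = sample(spec, 10_000, rng)
        assert chi_square_gof(draws, pmf_vector(spec)) > 0.01

    def test_binomial_case_gof(self, rng):
        draws = sample(CMPBSpec(7, 1.0, 1.0), 10_000, rng)
        assert chi_square_gof(draws, stats.binom.pmf(np.arange(8), 7, 0.5)) > 0.01

    def test_vectorized_matches_stepping_loop(self):
        # the shared-CDF searchsorted draw and the literal stepping
        # algorithm consume one uniform each and must agree draw-for-draw
        spec = CMPBSpec(9, 0.7, -0.8)
        a = sample(spec, 200, np.random.default_rng(11))
        rng = np.random.default_rng(11)
        b = np.array([sample_one(spec, rng) for _ in range(200)])
        assert np.array_equal(a, b)


class TestJointCountingPmf:
    def test_permutation_invariance(self):
        spec = CMPBSpec(6, 0.8, 1.7)
        z = np.array([1, 1, 0, 1, 0, 0])
        base = joint_counting_pmf(spec, z)
        rng = np.random.default_rng(2)
        for _ in range(5):
            assert joint_counting_pmf(spec, rng.permutation(z)) == pytest.approx(
                base, rel=1e-14
            )

    @pytest.mark.parametrize("nu", [-1.0, 0.5, 1.0, 2.0])
    def test_normalization_over_all_vectors(self, nu):
        spec = CMPBSpec(8, 1.3, nu)
        total = sum(
            joint_counting_pmf(spec, z) for z in itertools.product((0, 1), repeat=8)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_marginal_sum_reproduces_pmf_everywhere(self):
        spec = CMPBSpec(7, 0.6, -0.7)
        sums = np.zeros(8)
        for z in itertools.product((0, 1), repeat=7):
            sums[sum(z)] += joint_counting_pmf(spec, z)
        assert np.abs(sums - pmf_vector(spec)).max() < 1e-13

    def test_rejects_non_binary(self):
        spec = CMPBSpec(3, 1.0, 1.0)
        with pytest.raises(ValueError):
            joint_counting_pmf(spec, [0, 1, 2])


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=0, theta=1.0, nu=1.0),
            dict(n=3, theta=0.0, nu=1.0),
            dict(n=3, theta=-1.0, nu=1.0),
            dict(n=3, theta=np.inf, nu=1.0),
            dict(n=3, theta=1.0, nu=np.nan),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CMPBSpec(**kwargs)

    def test_reparameterizations(self):
        spec = CMPBSpec.from_alpha(5, 0.75, 2.0)
        assert spec.theta == pytest.approx(3.0)
        assert spec.alpha == pytest.approx(0.75)
        assert spec.lam == pytest.approx(3.0**0.5)
        with pytest.raises(ValueError):
            CMPBSpec(5, 1.0, 0.0).lam
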