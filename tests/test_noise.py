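"""Gauss-Markov error engine: closed forms, sampler laws, seed contract."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import insilico as isd
from insilico.noise import sample_error_sequence
from insilico.timeseries import TimeSeries


def constant_series(p: float, n: int, dt: float = 30.0) -> TimeSeries:
    return TimeSeries(0.0, dt, ("signal",), np.full((n, 1), p))


class TestCorrelationCoefficient:
    @pytest.mark.parametrize(
        "dt, tau, expected",
        [
            (30.0, 30.0, math.exp(-1.0)),
            (0.0, 30.0, 1.0),
            (30.0, math.inf, 1.0),
            (60.0, 30.0, math.exp(-2.0)),
        ],
    )
    def test_closed_form(self, dt, tau, expected):
        assert isd.correlation_coefficient(dt, tau) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("dt, tau", [(-1.0, 30.0), (30.0, 0.0), (30.0, -5.0)])
    def test_invalid_arguments(self, dt, tau):
        with pytest.raises(ValueError):
            isd.correlation_coefficient(dt, tau)

    @given(
        dt=st.floats(0.0, 1e4),
        tau=st.floats(1e-3, 1e6),
        delta=st.floats(1e-6, 1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_dt_and_tau(self, dt, tau, delta):
        rho = isd.correlation_coefficient(dt, tau)
        # mathematically rho > 0; exp underflows to 0.0 for dt/tau > ~745
        assert 0.0 <= rho <= 1.0
        if dt / tau < 700:
            assert rho > 0.0
        assert isd.correlation_coefficient(dt + delta, tau) <= rho
        assert isd.correlation_coefficient(dt, tau + delta) >= rho


class TestVarianceFunction:
    def test_arithmetic(self):
        assert isd.variance_function(1.0, 0.05) == pytest.approx(0.0025)
        assert isd.variance_function(0.0, 0.37) == 0.0
        assert isd.variance_function(-2.0, 0.1) == pytest.approx(0.04)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            isd.variance_function(1.0, -0.01)

    @given(
        p1=st.floats(-1e3, 1e3),
        p2=st.floats(-1e3, 1e3),
        eps=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_non_decreasing_in_magnitude(self, p1, p2, eps):
        lo, hi = sorted([abs(p1), abs(p2)])
        assert isd.variance_function(hi, eps) >= isd.variance_function(lo, eps)


class TestConditionalDistribution:
    def test_independence_recovers_marginal(self):
        d = isd.conditional_error_distribution(1.7, 1.0, 2.0, 0.0)
        assert d.mean == 0.0
        assert d.variance == pytest.approx(4.0)

    def test_perfect_correlation_is_deterministic(self):
        d = isd.conditional_error_distribution(0.3, 0.5, 0.5, 1.0)
        assert d.mean == pytest.approx(0.3)
        assert d.variance == pytest.approx(0.0, abs=1e-15)

    def test_zero_previous_sigma_restarts_chain(self):
        d = isd.conditional_error_distribution(0.0, 0.0, 2.0, 0.9)
        assert d.mean == 0.0
        assert d.variance == pytest.approx((1 - 0.81) * 4.0)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            isd.conditional_error_distribution(0.0, 1.0, 1.0, 1.5)

    def test_against_rejection_sampling_oracle(self, rng):
        """Conditioning the bivariate law on X0 ~ 2 must reproduce the
        closed-form conditional N(2.0, 3.0) for sigma0=1, sigma1=2, rho=0.5."""
        s0, s1, rho, x0 = 1.0, 2.0, 0.5, 2.0
        d = isd.conditional_error_distribution(x0, s0, s1, rho)
        assert d.mean == pytest.approx(2.0)
        assert d.variance == pytest.approx(3.0)

        # brute-force rejection sampling directly from the joint density
        def joint_pdf(a, b):
            q = (a / s0) ** 2 + (b / s1) ** 2 - 2 * rho * a * b / (s0 * s1)
            return np.exp(-q / (2 * (1 - rho**2))) / (
                2 * np.pi * s0 * s1 * math.sqrt(1 - rho**2)
            )

        n_prop = 12_000_000
        a = rng.uniform(-6 * s0, 6 * s0, n_prop)
        b = rng.uniform(-6 * s1, 6 * s1, n_prop)
        m = joint_pdf(0.0, 0.0)  # density maximum: envelope constant
        keep = rng.uniform(0, m, n_prop) < joint_pdf(a, b)
        a, b = a[keep], b[keep]
        window = 0.05
        oracle = b[np.abs(a - x0) < window]
        assert oracle.size > 500

        mc_se_mean = oracle.std(ddof=1) / math.sqrt(oracle.size)
        assert oracle.mean() == pytest.approx(d.mean, abs=3 * mc_se_mean + window)
        assert oracle.var(ddof=1) == pytest.approx(d.variance, rel=0.15)

        # two-sample test: our sampler vs the oracle
        ours = d.mean + math.sqrt(d.variance) * rng.standard_normal(oracle.size)
        assert stats.ks_2samp(oracle, ours).pvalue > 0.01


class TestSuperposeError:
    def test_zero_epsilon_is_identity(self, ideal_series):
        spec = isd.NoiseSpec(epsilon=0.0, tau=30.0)
        noisy = isd.superpose_error(ideal_series[0], spec, 1)
        np.testing.assert_array_equal(noisy.values, ideal_series[0].values)
        assert noisy.is_noisy

    def test_stationary_ar1_moments(self):
        """Constant ideal series: sample std -> eps*p and lag-1
        autocorrelation -> exp(-dt/tau), within 3 Monte-Carlo SEs."""
        n, eps, p = 100_000, 0.05, 1.0
        series = constant_series(p, n)
        noisy = isd.superpose_error(series, isd.NoiseSpec(eps, tau=30.0), seed=42)
        x = noisy.values[:, 0] - p
        rho = math.exp(-1.0)
        sigma = eps * p

        # mean: SE inflated by the correlation (factor 1 + 2*rho/(1-rho))
        se_mean = sigma * math.sqrt((1 + 2 * rho / (1 - rho)) / n)
        assert abs(x.mean()) < 3 * se_mean

        # std: asymptotic SE for an AR(1) Gaussian sequence
        s2 = rho**2 / (1 - rho**2)
        se_std = sigma * math.sqrt((1 + 2 * s2) / (2 * n))
        assert x.std(ddof=1) == pytest.approx(sigma, abs=3 * se_std)

        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        se_r1 = math.sqrt((1 - rho**2) / n)
        assert r1 == pytest.approx(rho, abs=3 * se_r1)

    def test_lag_k_correlation_decays_as_rho_power_k(self):
        n, rho = 200_000, math.exp(-1.0)
        series = constant_series(1.0, n)
        noisy = isd.superpose_error(series, isd.NoiseSpec(0.05, tau=30.0), seed=3)
        x = noisy.values[:, 0] - 1.0
        for lag in (1, 2, 3):
            r = np.corrcoef(x[:-lag], x[lag:])[0, 1]
            se = math.sqrt((1 - rho ** (2 * lag)) / n) * math.sqrt(
                1 + 2 * rho**2 / (1 - rho**2)
            )
            assert r == pytest.approx(rho**lag, abs=3 * se)

    def test_marginal_normality(self):
        series = constant_series(1.0, 50_000)
        noisy = isd.superpose_error(series, isd.NoiseSpec(0.05, tau=30.0), seed=11)
        x = noisy.values[:, 0] - 1.0
        assert stats.normaltest(x).pvalue > 0.01

    def test_no_variance_inflation_through_recursion(self):
        """Unconditional variance stays sigma^2 at every position, not just
        in stationarity: check across many short replicate paths."""
        rho = math.exp(-1.0)
        sigmas = np.full(20, 0.05)
        reps = 4000
        rng = np.random.default_rng(7)
        paths = np.array([sample_error_sequence(sigmas, rho, rng) for _ in range(reps)])
        variances = paths.var(axis=0, ddof=1)
        se_var = 0.05**2 * math.sqrt(2.0 / (reps - 1))
        assert np.all(np.abs(variances - 0.05**2) < 4 * se_var)

    def test_heteroscedastic_sigma_tracks_signal(self):
        """Relative mode: per-point error std follows eps*|p_i| even when the
        ideal value changes along the series."""
        p = np.concatenate([np.full(30, 2.0), np.full(30, 0.5)])
        series = TimeSeries(0.0, 30.0, ("signal",), p[:, None])
        reps = 3000
        errs = np.array(
            [
                isd.superpose_error(series, isd.NoiseSpec(0.1, tau=30.0), seed=s).values[:, 0] - p
                for s in range(reps)
            ]
        )
        stds = errs.std(axis=0, ddof=1)
        np.testing.assert_allclose(stds[:30], 0.2, rtol=0.1)
        np.testing.assert_allclose(stds[30:], 0.05, rtol=0.1)

    def test_seed_determinism(self, ideal_series):
        spec = isd.NoiseSpec(0.05, tau=30.0)
        a = isd.superpose_error(ideal_series[0], spec, 123)
        b = isd.superpose_error(ideal_series[0], spec, 123)
        c = isd.superpose_error(ideal_series[0], spec, 124)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_species_substreams_are_stable(self):
        """Adding a species never perturbs another species' error draws."""
        n = 50
        one = TimeSeries(0.0, 30.0, ("a",), np.ones((n, 1)))
        two = TimeSeries(0.0, 30.0, ("a", "b"), np.ones((n, 2)))
        spec = isd.NoiseSpec(0.05, tau=30.0)
        e1 = isd.superpose_error(one, spec, 9).values[:, 0]
        e2 = isd.superpose_error(two, spec, 9).values[:, 0]
        np.testing.assert_array_equal(e1, e2)

    def test_species_columns_independent(self):
        n = 40_000
        two = TimeSeries(0.0, 30.0, ("a", "b"), np.ones((n, 2)))
        noisy = isd.superpose_error(two, isd.NoiseSpec(0.05, tau=30.0), 5)
        x = noisy.values - 1.0
        r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        assert abs(r) < 3.0 / math.sqrt(n)

    def test_noisy_input_rejected(self, ideal_series):
        spec = isd.NoiseSpec(0.05, tau=30.0)
        noisy = isd.superpose_error(ideal_series[0], spec, 1)
        with pytest.raises(ValueError, match="already noisy"):
            isd.superpose_error(noisy, spec, 1)

    def test_clip_at_zero_flag(self):
        series = constant_series(0.01, 2000)
        spec = isd.NoiseSpec(epsilon=0.5, tau=30.0)
        free = isd.superpose_error(series, spec, 2)
        clipped = isd.superpose_error(series, spec, 2, clip_at_zero=True)
        assert free.values.min() < 0  # negative readings allowed by default
        assert clipped.values.min() >= 0
        np.testing.assert_array_equal(clipped.values, np.maximum(free.values, 0.0))

    def test_sampler_matches_conditional_distribution_op(self):
        """The inlined recursion in sample_error_sequence must stay in
        lock-step with conditional_error_distribution."""
        rho = 0.6
        sigmas = np.array([0.1, 0.0, 0.3, 0.2])
        rng = np.random.default_rng(0)
        x = sample_error_sequence(sigmas, rho, rng)
        innov = np.random.default_rng(0).standard_normal(4)
        expected = np.zeros(4)
        expected[0] = sigmas[0] * innov[0]
        for i in range(1, 4):
            d = isd.conditional_error_distribution(expected[i - 1], sigmas[i - 1], sigmas[i], rho)
            expected[i] = d.mean + math.sqrt(d.variance) * innov[i]
        np.testing.assert_allclose(x, expected, rtol=1e-12)
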