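import numpy as np
import pytest
from scipy.optimize import brentq, minimize

from cogwear.performance import (
    BehavioralSeries,
    PerformanceParams,
    filter_forward,
    fit_em,
    grid_posterior_oracle,
    maximize_q2,
    q2_value,
    smooth_backward,
)
from cogwear.statespace import posterior_moments, sigmoid_probability
from cogwear.synthetic import SessionSchedule, simulate_performance_trajectory


def _random_series(seed, K=8, p_missing=0.0):
    rng = np.random.default_rng(seed)
    m = rng.integers(0, 2, K)
    t = np.exp(rng.normal(0.0, 0.3, K))
    if p_missing:
        t[rng.random(K) < p_missing] = np.nan
    return BehavioralSeries(m=m, t=t)


def _params(seed):
    # jitter around the realistic n-back regime
    rng = np.random.default_rng(seed + 777)
    return PerformanceParams(
        rho=rng.uniform(0.9, 0.99),
        sigma_w2=rng.uniform(0.02, 0.1),
        alpha0=rng.normal(0, 0.2),
        alpha1=rng.uniform(-0.5, -0.1),
        sigma_delta2=rng.uniform(0.02, 0.1),
        p0=rng.uniform(0.5, 0.8),
    )


class TestSeriesValidation:
    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            BehavioralSeries(m=[0, 2], t=[0.5, 0.5])

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(ValueError):
            BehavioralSeries(m=[0, 1], t=[0.5, -0.1])

    def test_missing_rt_allowed(self):
        s = BehavioralSeries(m=[0, 1], t=[np.nan, 0.5])
        assert np.isnan(s.log_rt[0])


class TestFilter:
    def test_predicted_variance_arithmetic(self):
        # rho=1, s0=0.1, sigma_w2=0.05 -> predicted variance 0.15
        params = PerformanceParams(rho=1.0, sigma_w2=0.05, sigma_delta2=0.1)
        series = BehavioralSeries(m=[1], t=[0.5])
        _, _, pv = filter_forward(series, params, z0=0.0, s0=0.1)
        assert pv[0] == pytest.approx(0.15, abs=1e-12)

    def test_variance_contraction(self):
        params = _params(0)
        series = _random_series(0, K=12)
        est, _, pv = filter_forward(series, params)
        assert np.all(est.variance <= pv + 1e-12)

    def test_binary_only_limit_matches_independent_filter(self):
        """With an uninformative continuous channel the mixed filter reduces
        to a Bernoulli-observation filter implemented here from scratch."""
        params = PerformanceParams(
            rho=0.9, sigma_w2=0.2, alpha0=0.0, alpha1=-0.3,
            sigma_delta2=1e12, p0=0.6,
        )
        series = _random_series(1, K=10)
        est, _, _ = filter_forward(series, params)

        mu = params.mu
        z, s2 = 0.0, params.sigma_w2
        ref = []
        for m in series.m:
            zp = params.rho * z
            sp = params.rho**2 * s2 + params.sigma_w2

            def g(x):
                return x - zp - sp * (m - sigmoid_probability(x, mu))

            z = brentq(g, zp - sp - 1, zp + sp + 1, xtol=1e-12)
            p = sigmoid_probability(z, mu)
            s2 = 1.0 / (1.0 / sp + p * (1 - p))
            ref.append(z)
        assert np.max(np.abs(est.mean - np.array(ref))) <= 1e-4

    @pytest.mark.parametrize("seed", range(5))
    def test_filter_matches_grid_quadrature(self, seed):
        params = _params(seed)
        series = _random_series(seed, K=6)
        est, _, _ = filter_forward(series, params)
        oracle = grid_posterior_oracle(series, params)
        assert np.max(np.abs(est.mean - oracle.filtered_mean)) < 1e-2


class TestSmoother:
    def test_anchor_at_final_filtered_step(self):
        params = _params(2)
        series = _random_series(2, K=7)
        filt, pm, pv = filter_forward(series, params)
        sm, _ = smooth_backward(filt, pm, pv, params)
        assert sm.mean[-1] == filt.mean[-1]
        assert sm.variance[-1] == filt.variance[-1]

    def test_uninformative_prior_limit(self):
        # huge process noise: smoothing cannot borrow strength across steps
        params = PerformanceParams(rho=0.9, sigma_w2=1e6, sigma_delta2=0.1)
        series = _random_series(3, K=8)
        filt, pm, pv = filter_forward(series, params)
        sm, _ = smooth_backward(filt, pm, pv, params)
        assert np.max(np.abs(sm.mean - filt.mean)) < 1e-3

    @pytest.mark.parametrize("seed", range(5))
    def test_smoother_matches_grid_quadrature(self, seed):
        params = _params(seed + 10)
        series = _random_series(seed + 10, K=6)
        filt, pm, pv = filter_forward(series, params)
        sm, _ = smooth_backward(filt, pm, pv, params)
        oracle = grid_posterior_oracle(series, params)
        assert np.max(np.abs(sm.mean - oracle.smoothed_mean)) < 1e-2


class TestGridOracle:
    def test_resolution_convergence(self):
        params = _params(4)
        series = _random_series(4, K=5)
        a = grid_posterior_oracle(series, params, n_points=2001)
        b = grid_posterior_oracle(series, params, n_points=4001)
        assert np.max(np.abs(a.smoothed_mean - b.smoothed_mean)) < 1e-6

    def test_single_trial_information_direction(self):
        params = PerformanceParams(rho=1.0, sigma_w2=0.5, sigma_delta2=1e12,
                                   p0=0.5)
        up = grid_posterior_oracle(
            BehavioralSeries(m=[1], t=[np.nan]), params
        )
        down = grid_posterior_oracle(
            BehavioralSeries(m=[0], t=[np.nan]), params
        )
        assert up.smoothed_mean[0] > 0 > down.smoothed_mean[0]

    def test_sampling_reproduces_second_moments(self):
        params = _params(5)
        series = _random_series(5, K=5)
        filt, pm, pv = filter_forward(series, params)
        sm, B = smooth_backward(filt, pm, pv, params)
        ez2, _ = posterior_moments(sm.mean, sm.variance, B)
        oracle = grid_posterior_oracle(series, params)
        draws = oracle.sample(np.random.default_rng(0), 4000)
        emp = (draws**2).mean(axis=0)
        se = (draws**2).std(axis=0) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(emp - ez2) < 3 * se + 1e-2)


class TestMStep:
    def test_point_mass_moments_recover_regression(self):
        rng = np.random.default_rng(6)
        K = 200
        z = rng.normal(0, 1, K)
        a0, a1 = 0.25, -0.4
        t = np.exp(a0 + a1 * z)  # noise-free continuous channel
        series = BehavioralSeries(m=rng.integers(0, 2, K), t=t)
        ez2 = z**2
        ezz = z[1:] * z[:-1]
        params = maximize_q2(series, z, ez2, ezz, _params(6))
        assert params.alpha0 == pytest.approx(a0, abs=1e-8)
        assert params.alpha1 == pytest.approx(a1, abs=1e-8)
        # zero residuals flagged by flooring the variance
        assert params.sigma_delta2 <= 1e-10

    def test_closed_form_maximizes_q2(self):
        """A general-purpose optimizer cannot improve on the closed form."""
        params = _params(7)
        series = _random_series(7, K=40)
        filt, pm, pv = filter_forward(series, params)
        sm, B = smooth_backward(filt, pm, pv, params)
        ez = sm.mean
        ez2, ezz = posterior_moments(ez, sm.variance, B)
        closed = maximize_q2(series, ez, ez2, ezz, params)
        q_closed = q2_value(series, ez, ez2, ezz, sm.variance, closed)

        def neg_q(theta):
            a0, a1, log_sd2, rho, log_sw2 = theta
            cand = PerformanceParams(
                rho=rho, sigma_w2=np.exp(log_sw2), alpha0=a0, alpha1=a1,
                sigma_delta2=np.exp(log_sd2), p0=params.p0,
            )
            return -q2_value(series, ez, ez2, ezz, sm.variance, cand)

        x0 = np.array([
            closed.alpha0 + 0.05, closed.alpha1 - 0.05,
            np.log(closed.sigma_delta2) + 0.1, closed.rho - 0.02,
            np.log(closed.sigma_w2) + 0.1,
        ])
        res = minimize(neg_q, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        assert q_closed >= -res.fun - 1e-6


class TestEM:
    def test_single_iteration_at_infinite_tolerance(self):
        _, series = simulate_performance_trajectory(
            SessionSchedule(n_trials_per_session=100, sessions=(("s", 1.0),)),
            seed=0,
        )
        _, _, diag = fit_em(series, tol=np.inf, max_iter=50)
        assert diag.n_iter == 1
        assert diag.converged

    def test_truth_initialization_converges_quickly(self):
        # near-noiseless reaction times pin the state, so EM started at the
        # generating parameters is already at its fixed point
        sched = SessionSchedule(n_trials_per_session=400, sessions=(("s", 1.0),))
        truth, series = simulate_performance_trajectory(
            sched, seed=1, sigma_w2=0.05, sigma_delta2=1e-4,
        )
        init = PerformanceParams(
            rho=0.98, sigma_w2=0.05, alpha0=0.0, alpha1=-0.3,
            sigma_delta2=1e-4, p0=series.empirical_p0(),
        )
        _, _, diag = fit_em(series, init=init, tol=5e-2, max_iter=20)
        assert diag.n_iter <= 5

    def test_q2_mstep_ascent(self):
        """Every M-step improves Q2 under the E-step that produced it."""
        sched = SessionSchedule(n_trials_per_session=300, sessions=(("s", 1.0),))
        _, series = simulate_performance_trajectory(sched, seed=2)
        _, _, diag = fit_em(series, tol=1e-6, max_iter=40)
        assert np.all(diag.q_improvement >= -1e-6)

    def test_recovers_generating_dynamics(self):
        sched = SessionSchedule(n_trials_per_session=2000, sessions=(("s", 1.0),))
        truth, series = simulate_performance_trajectory(sched, seed=0)
        params, sm, _ = fit_em(series, tol=1e-5, max_iter=60)
        assert abs(params.rho - 0.98) <= 0.05
        assert params.alpha1 < 0
        assert abs(params.alpha1 - (-0.3)) / 0.3 <= 0.3
        assert np.corrcoef(sm.mean, truth.z)[0, 1] > 0.7

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_em(BehavioralSeries(m=[1] * 5, t=[0.5] * 5))
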