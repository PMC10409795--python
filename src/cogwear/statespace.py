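"""Shared machinery for the scalar latent-state models.

Both latent-state estimators in this package (cognitive performance from
n-back behavior, cognitive arousal from electrodermal impulses) are scalar
first-order Gaussian state-space models observed through a Bernoulli channel
(via a sigmoid link) plus an optional conditionally-Gaussian continuous
channel.  This module holds the pieces they share:

* the sigmoid link and its logit inverse,
* the implicit filter update ``x = x_pred + c0 + c1*(m - sigmoid(x + offset))``
  solved by Newton–Raphson with a bisection fallback,
* the fixed-interval (RTS-style) smoother recursions,
* posterior second moments used by the EM M-steps,
* a dense-grid forward–backward quadrature that computes the exact posterior
  for short series, used as an independent numerical oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "sigmoid_probability",
    "baseline_offset",
    "LatentStateEstimate",
    "EMDiagnostics",
    "solve_implicit_update",
    "smooth_backward_gaussian",
    "posterior_moments",
    "GridPosterior",
    "grid_posterior",
]


def sigmoid_probability(z, mu):
    """Probability 1 / (1 + exp(-(z + mu))) of a success at state ``z``.

    Strictly increasing in ``z``; saturates (never raises) at extreme inputs.
    """
    return expit(np.asarray(z, dtype=float) + mu)


def baseline_offset(p0: float) -> float:
    """Logit of the baseline success probability, ``log(p0 / (1 - p0))``.

    The state-space models hold this offset fixed at the empirical average
    success rate so the latent state is identified as a deviation from
    baseline.
    """
    p0 = float(p0)
    if not 0.0 < p0 < 1.0:
        raise ValueError(
            f"baseline probability must lie strictly in (0, 1), got {p0}; "
            "clip degenerate empirical rates to [1/(2K), 1 - 1/(2K)] first"
        )
    return float(np.log(p0 / (1.0 - p0)))


@dataclass
class LatentStateEstimate:
    """Per-step posterior summary of a scalar latent state.

    ``mean`` and ``variance`` are the Gaussian-approximate posterior moments
    (filtered or smoothed); ``prob`` maps the mean through the sigmoid link;
    ``ci_low``/``ci_high`` map mean +/- 1.96 sd through the same link, so they
    bracket ``prob`` on the probability scale.
    """

    mean: np.ndarray
    variance: np.ndarray
    offset: float
    prob: np.ndarray = field(init=False)
    ci_low: np.ndarray = field(init=False)
    ci_high: np.ndarray = field(init=False)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape:
            raise ValueError("mean and variance must have equal length")
        if np.any(self.variance <= 0):
            raise ValueError("posterior variances must be strictly positive")
        sd = np.sqrt(self.variance)
        self.prob = sigmoid_probability(self.mean, self.offset)
        self.ci_low = sigmoid_probability(self.mean - 1.96 * sd, self.offset)
        self.ci_high = sigmoid_probability(self.mean + 1.96 * sd, self.offset)

    def __len__(self) -> int:
        return self.mean.size


@dataclass
class EMDiagnostics:
    """Bookkeeping from an EM fit.

    ``q_trajectory`` holds the maximized expected complete-data
    log-likelihood per iteration; ``q_improvement`` holds, per iteration, the
    M-step gain Q(theta_new) - Q(theta_old) evaluated under the same E-step
    moments.  The EM ascent guarantee is that every entry of
    ``q_improvement`` is nonnegative (the cross-iteration trajectory may
    drift as the E-step distribution changes).
    """

    n_iter: int
    q_trajectory: np.ndarray
    converged: bool
    final_param_delta: float
    q_improvement: np.ndarray = field(default_factory=lambda: np.empty(0))


def solve_implicit_update(
    x_pred: float,
    c0: float,
    c1: float,
    m: float,
    offset: float,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> float:
    """Solve ``x = x_pred + c0 + c1 * (m - sigmoid(x + offset))`` for ``x``.

    This is the implicit mean update shared by every filter in the package:
    the Bernoulli innovation ``m - p`` is evaluated at the *updated* state, so
    the update equation must be solved numerically.  With ``c1 >= 0`` the root
    is unique (the residual is strictly increasing).  Newton–Raphson from the
    predicted mean, falling back to bracketed bisection (brentq) if Newton
    leaves the bracket or stalls.
    """
    if c1 < 0:
        raise ValueError("Bernoulli gain c1 must be nonnegative")

    def g(x):
        return x - x_pred - c0 - c1 * (m - expit(x + offset))

    x = x_pred
    for _ in range(max_iter):
        p = expit(x + offset)
        gx = x - x_pred - c0 - c1 * (m - p)
        gp = 1.0 + c1 * p * (1.0 - p)
        step = gx / gp
        x_new = x - step
        if abs(step) < tol:
            return x_new
        x = x_new
    # Newton stalled; the root is bracketed by the extreme innovations.
    lo = x_pred + c0 + c1 * (m - 1.0) - tol
    hi = x_pred + c0 + c1 * m + tol
    try:
        return float(brentq(g, lo, hi, xtol=tol))
    except ValueError as exc:  # pragma: no cover - defensive
        raise FloatingPointError(
            f"implicit filter update failed to converge (x_pred={x_pred})"
        ) from exc


def smooth_backward_gaussian(
    filt_mean: np.ndarray,
    filt_var: np.ndarray,
    pred_mean: np.ndarray,
    pred_var: np.ndarray,
    rho: float,
):
    """Fixed-interval smoother for a scalar AR(1) state.

    ``pred_mean[k]``/``pred_var[k]`` are the one-step predictions used when
    filtering step ``k``.  Gains are ``B_k = rho * s2_{k|k} / s2_{k+1|k}``;
    the final step anchors at the filtered estimate.  Returns
    ``(smoothed_mean, smoothed_var, gains)`` where ``gains`` has length K-1.
    """
    filt_mean = np.asarray(filt_mean, float)
    filt_var = np.asarray(filt_var, float)
    K = filt_mean.size
    sm = filt_mean.copy()
    sv = filt_var.copy()
    B = np.empty(max(K - 1, 0))
    for k in range(K - 2, -1, -1):
        pv = pred_var[k + 1]
        if pv <= 0:
            raise FloatingPointError(f"zero predicted variance at step {k + 1}")
        B[k] = rho * filt_var[k] / pv
        sm[k] = filt_mean[k] + B[k] * (sm[k + 1] - pred_mean[k + 1])
        sv[k] = filt_var[k] + B[k] ** 2 * (sv[k + 1] - pv)
    return sm, sv, B


def posterior_moments(smoothed_mean, smoothed_var, gains):
    """Second moments needed by the EM M-steps.

    ``E[z_k^2] = z_{k|K}^2 + s2_{k|K}`` and
    ``E[z_{k+1} z_k] = z_{k+1|K} z_{k|K} + B_k s2_{k+1|K}``.
    """
    sm = np.asarray(smoothed_mean, float)
    sv = np.asarray(smoothed_var, float)
    B = np.asarray(gains, float)
    if sm.shape != sv.shape or B.size != max(sm.size - 1, 0):
        raise ValueError("moment inputs have inconsistent lengths")
    ez2 = sm**2 + sv
    ezz = sm[1:] * sm[:-1] + B * sv[1:]
    return ez2, ezz


@dataclass
class GridPosterior:
    """Exact (quadrature) posterior for a short scalar state-space series."""

    grid: np.ndarray
    filtered_mean: np.ndarray
    filtered_var: np.ndarray
    smoothed_mean: np.ndarray
    smoothed_var: np.ndarray
    # per-step smoothed densities on the grid (rows sum to 1)
    smoothed_pmf: np.ndarray
    # forward filtered pmfs and transition matrix kept for backward sampling
    _alpha: np.ndarray
    _trans: np.ndarray

    def sample(self, rng: np.random.Generator, n_samples: int) -> np.ndarray:
        """Draw joint trajectories by backward sampling; shape (n, K)."""
        K, G = self._alpha.shape
        out = np.empty((n_samples, K))
        idx = rng.choice(G, size=n_samples, p=self._alpha[-1])
        out[:, -1] = self.grid[idx]
        for k in range(K - 2, -1, -1):
            # p(z_k | z_{k+1}) on the grid, per sample
            w = self._alpha[k][None, :] * self._trans[idx, :]
            w /= w.sum(axis=1, keepdims=True)
            cum = np.cumsum(w, axis=1)
            u = rng.random(n_samples)[:, None]
            idx = (u > cum).sum(axis=1)
            out[:, k] = self.grid[idx]
        return out


def grid_posterior(
    loglik_fn,
    n_steps: int,
    rho: float,
    process_var: float,
    init_mean: float,
    init_var: float,
    n_points: int = 2001,
    span_sd: float = 6.0,
) -> GridPosterior:
    """Exact posterior of an AR(1) state by dense-grid forward–backward.

    ``loglik_fn(k, grid)`` returns the per-step observation log-likelihood
    evaluated on the supplied state grid.  Intended as an independent
    numerical oracle for series of length <= ~12; cost is
    O(K n_points^2).  Raises if posterior mass touches the grid boundary
    (grid too narrow/coarse).
    """
    if n_points < 2000:
        raise ValueError("oracle grid needs >= 2000 points")
    K = int(n_steps)
    # Span covers the prior marginal at the final step plus slack.
    var_horizon = init_var
    for _ in range(K):
        var_horizon = rho**2 * var_horizon + process_var
    half = span_sd * np.sqrt(init_var + var_horizon) + 6.0
    grid = np.linspace(init_mean - half, init_mean + half, n_points)
    obs_loglik = np.vstack([loglik_fn(k, grid) for k in range(K)])
    if obs_loglik.shape != (K, n_points):
        raise ValueError("loglik_fn must return one value per grid point")

    # Transition density matrix T[i, j] = p(z' = grid[i] | z = grid[j]),
    # column-normalized so each conditional sums to one on the grid.
    diff = grid[:, None] - rho * grid[None, :]
    trans = np.exp(-0.5 * diff**2 / process_var)
    trans /= trans.sum(axis=0, keepdims=True)

    # state prior at step 0: z_1 ~ N(rho*init_mean, rho^2*init_var + process_var)
    prior_var = rho**2 * init_var + process_var
    log_prior = -0.5 * (grid - rho * init_mean) ** 2 / prior_var

    alpha = np.empty((K, n_points))
    a = log_prior + obs_loglik[0]
    a = np.exp(a - a.max())
    a /= a.sum()
    alpha[0] = a
    for k in range(1, K):
        pred = trans @ alpha[k - 1]
        lw = obs_loglik[k] - obs_loglik[k].max()
        a = pred * np.exp(lw)
        a /= a.sum()
        alpha[k] = a

    beta = np.empty((K, n_points))
    beta[-1] = 1.0
    for k in range(K - 2, -1, -1):
        lw = obs_loglik[k + 1] - obs_loglik[k + 1].max()
        msg = trans.T @ (np.exp(lw) * beta[k + 1])
        beta[k] = msg / msg.max()

    smoothed = alpha * beta
    smoothed /= smoothed.sum(axis=1, keepdims=True)

    edge_mass = smoothed[:, [0, -1]].sum()
    if edge_mass > 1e-6:
        raise ValueError(
            f"posterior mass {edge_mass:.2e} at grid boundary; widen the grid"
        )

    def _moments(pmf):
        mean = pmf @ grid
        var = pmf @ grid**2 - mean**2
        return mean, var

    fm, fv = _moments(alpha)
    sm, sv = _moments(smoothed)
    return GridPosterior(
        grid=grid,
        filtered_mean=fm,
        filtered_var=fv,
        smoothed_mean=sm,
        smoothed_var=sv,
        smoothed_pmf=smoothed,
        _alpha=alpha,
        _trans=trans,
    )
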