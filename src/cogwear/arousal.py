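"""Latent cognitive arousal estimation from electrodermal neural impulses.

The arousal state x_j follows a random walk

    x_{j+1} = x_j + eps_j,          eps_j ~ N(0, sigma_eps^2),

observed through a marked point process on a uniform grid: impulse
occurrence n_j ~ Bernoulli(a_j) with a_j = 1/(1+exp(-(x_j + beta))), and,
where an impulse occurs, a Gaussian mark (amplitude, microsiemens)

    r_j = gamma0 + gamma1 * x_j + v_j,   v_j ~ N(0, sigma_v^2).

beta is fixed at the logit of the empirical impulse rate a0.  The filter
branches on n_j: a Bernoulli-only update where no impulse occurred, and a
joint Bernoulli+Gaussian update (gain C_j) at impulse steps; both mean
updates are implicit and solved by Newton–Raphson.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .statespace import (
    EMDiagnostics,
    LatentStateEstimate,
    baseline_offset,
    grid_posterior,
    posterior_moments,
    sigmoid_probability,
    smooth_backward_gaussian,
    solve_implicit_update,
)

log = logging.getLogger(__name__)

__all__ = [
    "ImpulseSeries",
    "ArousalParams",
    "filter_forward",
    "smooth_backward",
    "maximize_q1",
    "fit_em",
    "q1_value",
    "grid_posterior_oracle",
    "read_impulses_csv",
    "write_estimates",
]


@dataclass
class ImpulseSeries:
    """Marked point process on a uniform grid.

    ``n`` is the 0/1 occurrence indicator; ``r`` holds the mark amplitude in
    microsiemens where ``n == 1`` and NaN elsewhere; ``t_grid`` is the grid
    step in seconds.
    """

    n: np.ndarray
    r: np.ndarray
    t_grid: float = 0.25

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        if self.n.shape != self.r.shape:
            raise ValueError("indicator and mark arrays must align")
        if not np.isin(self.n, (0, 1)).all():
            raise ValueError("occurrence indicator must be binary")
        if np.any(np.isfinite(self.r) != (self.n == 1)):
            raise ValueError("marks must be present exactly where n == 1")
        if self.t_grid <= 0:
            raise ValueError("grid step must be positive")

    def __len__(self) -> int:
        return self.n.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.t_grid

    def empirical_a0(self) -> float:
        J = len(self)
        return float(np.clip(self.n.mean(), 1.0 / (2 * J), 1 - 1.0 / (2 * J)))


@dataclass
class ArousalParams:
    sigma_eps2: float = 0.01
    gamma0: float = 0.3
    gamma1: float = 0.5
    sigma_v2: float = 0.01
    a0: float = 0.12

    def __post_init__(self):
        if self.sigma_eps2 <= 0 or self.sigma_v2 <= 0:
            raise ValueError("noise variances must be strictly positive")
        if not 0.0 < self.a0 < 1.0:
            raise ValueError("baseline impulse probability must be in (0, 1)")

    @property
    def beta(self) -> float:
        return baseline_offset(self.a0)

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_eps2, self.gamma0, self.gamma1, self.sigma_v2])


def filter_forward(
    series: ImpulseSeries,
    params: ArousalParams,
    x0: float = 0.0,
    s0: float | None = None,
):
    """Forward filter; returns (estimate, pred_mean, pred_var)."""
    if len(series) == 0:
        raise ValueError("empty impulse series")
    J = len(series)
    beta = params.beta
    se2 = params.sigma_eps2
    g0, g1, sv2 = params.gamma0, params.gamma1, params.sigma_v2
    if s0 is None:
        s0 = se2

    fm = np.empty(J)
    fv = np.empty(J)
    pm = np.empty(J)
    pv = np.empty(J)
    x, s2 = x0, s0
    for j in range(J):
        xp = x
        sp = s2 + se2
        pm[j], pv[j] = xp, sp
        if series.n[j] == 1:
            C = sp / (g1**2 * sp + sv2)
            c1 = C * sv2
            c0 = C * g1 * (series.r[j] - g0 - g1 * xp)
            x = solve_implicit_update(xp, c0, c1, 1.0, beta)
            a = sigmoid_probability(x, beta)
            s2 = 1.0 / (1.0 / sp + a * (1 - a) + g1**2 / sv2)
        else:
            x = solve_implicit_update(xp, 0.0, sp, 0.0, beta)
            a = sigmoid_probability(x, beta)
            s2 = 1.0 / (1.0 / sp + a * (1 - a))
        fm[j], fv[j] = x, s2
    est = LatentStateEstimate(mean=fm, variance=fv, offset=beta)
    return est, pm, pv


def smooth_backward(filtered, pred_mean, pred_var, params: ArousalParams):
    """Fixed-interval smoother (random-walk gains A_j); returns (estimate, A)."""
    sm, sv, A = smooth_backward_gaussian(
        filtered.mean, filtered.variance, pred_mean, pred_var, rho=1.0
    )
    return LatentStateEstimate(mean=sm, variance=sv, offset=params.beta), A


def maximize_q1(
    series: ImpulseSeries,
    ex: np.ndarray,
    ex2: np.ndarray,
    exx: np.ndarray,
    params: ArousalParams,
    x0: float = 0.0,
) -> ArousalParams:
    """Closed-form M-step for {gamma0, gamma1, sigma_v^2, sigma_eps^2}.

    The mark regression runs over the impulse steps only; the process noise
    uses expected squared increments over every step.  ``beta`` stays fixed.
    """
    on = series.n == 1
    n_on = int(on.sum())
    if n_on < 2:
        raise ValueError("need at least two impulses to fit the mark model")
    ro, exo, ex2o = series.r[on], ex[on], ex2[on]
    A = np.array([[n_on, exo.sum()], [exo.sum(), ex2o.sum()]])
    b = np.array([ro.sum(), (ro * exo).sum()])
    if abs(np.linalg.det(A)) < 1e-12 * max(1.0, ex2o.sum()) ** 2:
        raise np.linalg.LinAlgError("degenerate normal equations for (g0, g1)")
    gamma0, gamma1 = np.linalg.solve(A, b)
    resid2 = (
        ro**2
        - 2 * ro * (gamma0 + gamma1 * exo)
        + gamma0**2
        + 2 * gamma0 * gamma1 * exo
        + gamma1**2 * ex2o
    )
    sigma_v2 = float(np.maximum(resid2.mean(), 0.0))
    if sigma_v2 == 0.0:
        log.warning("degenerate mark channel: zero residual variance")
        sigma_v2 = 1e-12

    e_prev2 = np.concatenate([[x0**2], ex2[:-1]])
    e_cross = np.concatenate([[x0 * ex[0]], exx])
    sigma_eps2 = float((ex2 - 2 * e_cross + e_prev2).mean())
    if sigma_eps2 <= 0:
        log.warning("degenerate process noise estimate; flooring")
        sigma_eps2 = 1e-12
    return replace(
        params,
        sigma_eps2=sigma_eps2,
        gamma0=float(gamma0),
        gamma1=float(gamma1),
        sigma_v2=sigma_v2,
    )


def q1_value(
    series: ImpulseSeries,
    ex: np.ndarray,
    ex2: np.ndarray,
    exx: np.ndarray,
    sv: np.ndarray,
    params: ArousalParams,
    x0: float = 0.0,
) -> float:
    """Expected complete-data log-likelihood Q1 (delta-rule Bernoulli term)."""
    beta = params.beta
    a = sigmoid_probability(ex, beta)
    bern = series.n * (beta + ex) - np.logaddexp(0.0, beta + ex) - 0.5 * sv * a * (1 - a)
    on = series.n == 1
    ro, exo, ex2o = series.r[on], ex[on], ex2[on]
    g0, g1, sv2 = params.gamma0, params.gamma1, params.sigma_v2
    resid2 = (
        ro**2 - 2 * ro * (g0 + g1 * exo) + g0**2 + 2 * g0 * g1 * exo + g1**2 * ex2o
    )
    mark = -0.5 * on.sum() * np.log(2 * np.pi * sv2) - resid2.sum() / (2 * sv2)
    e_prev2 = np.concatenate([[x0**2], ex2[:-1]])
    e_cross = np.concatenate([[x0 * ex[0]], exx])
    innov2 = ex2 - 2 * e_cross + e_prev2
    se2 = params.sigma_eps2
    proc = -0.5 * len(series) * np.log(2 * np.pi * se2) - innov2.sum() / (2 * se2)
    return float(bern.sum() + mark + proc)


def _initial_params(series: ImpulseSeries) -> ArousalParams:
    marks = series.r[series.n == 1]
    var_r = float(np.var(marks)) if marks.size > 1 else 0.01
    return ArousalParams(
        sigma_eps2=1e-2,
        gamma0=float(marks.mean()) if marks.size else 0.0,
        gamma1=0.1,
        sigma_v2=max(var_r / 2, 1e-4),
        a0=series.empirical_a0(),
    )


def fit_em(
    series: ImpulseSeries,
    init: ArousalParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
):
    """EM fit; returns (params, smoothed estimate, diagnostics)."""
    if len(series) < 50 or int(series.n.sum()) < 5:
        raise ValueError("EM needs >= 50 steps with >= 5 impulses")
    params = init if init is not None else _initial_params(series)
    params = replace(params, a0=series.empirical_a0())
    q_traj = []
    q_gain = []
    converged = False
    delta = np.inf
    for it in range(1, max_iter + 1):
        filtered, pm, pv = filter_forward(series, params)
        smoothed, A = smooth_backward(filtered, pm, pv, params)
        ex = smoothed.mean
        ex2, exx = posterior_moments(ex, smoothed.variance, A)
        new = maximize_q1(series, ex, ex2, exx, params)
        if not np.all(np.isfinite(new.as_array())):
            raise FloatingPointError(f"EM diverged at iteration {it}")
        q_new = q1_value(series, ex, ex2, exx, smoothed.variance, new)
        q_old = q1_value(series, ex, ex2, exx, smoothed.variance, params)
        q_traj.append(q_new)
        q_gain.append(q_new - q_old)
        old_a, new_a = params.as_array(), new.as_array()
        # relative change with an absolute floor so near-zero parameters
        # (e.g. a zero intercept) do not stall convergence detection
        delta = float(np.max(np.abs(new_a - old_a) / np.maximum(np.abs(old_a), 1e-2)))
        params = new
        if delta < tol:
            converged = True
            break
    filtered, pm, pv = filter_forward(series, params)
    smoothed, _ = smooth_backward(filtered, pm, pv, params)
    diag = EMDiagnostics(
        n_iter=it,
        q_trajectory=np.asarray(q_traj),
        converged=converged,
        final_param_delta=delta,
        q_improvement=np.asarray(q_gain),
    )
    return params, smoothed, diag


def grid_posterior_oracle(
    series: ImpulseSeries,
    params: ArousalParams,
    x0: float = 0.0,
    s0: float | None = None,
    n_points: int = 2001,
):
    """Exact filtered/smoothed posterior by dense-grid quadrature (J <= 12)."""
    if len(series) > 12:
        raise ValueError("grid oracle is restricted to short series")
    beta = params.beta
    if s0 is None:
        s0 = params.sigma_eps2

    def loglik(j, grid):
        a = sigmoid_probability(grid, beta)
        if series.n[j] == 1:
            resid = series.r[j] - params.gamma0 - params.gamma1 * grid
            return np.log(a) - 0.5 * resid**2 / params.sigma_v2
        return np.log1p(-a)

    return grid_posterior(
        loglik, len(series), 1.0, params.sigma_eps2, x0, s0, n_points=n_points
    )


def read_impulses_csv(path, t_grid: float | None = None) -> ImpulseSeries:
    """Read an impulse table ``time_s,amplitude_uS`` on a uniform grid."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    amp = df["amplitude_uS"].to_numpy(float)
    if t_grid is None:
        if t.size < 2:
            raise ValueError("cannot infer grid step from fewer than 2 rows")
        t_grid = float(np.median(np.diff(t)))
    n = (amp > 0).astype(int)
    r = np.where(n == 1, amp, np.nan)
    return ImpulseSeries(n=n, r=r, t_grid=t_grid)


def write_estimates(outdir, smoothed: LatentStateEstimate, params: ArousalParams, t_grid: float):
    """Write per-step arousal CSV and a parameters JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "time_s": np.arange(len(smoothed)) * t_grid,
            "x_mean": smoothed.mean,
            "x_var": smoothed.variance,
            "a_prob": smoothed.prob,
        }
    ).to_csv(outdir / "arousal_estimates.csv", index=False)
    blob = {
        "sigma_eps2": params.sigma_eps2,
        "gamma0": params.gamma0,
        "gamma1": params.gamma1,
        "sigma_v2": params.sigma_v2,
        "a0": params.a0,
        "beta": params.beta,
    }
    (outdir / "arousal_params.json").write_text(json.dumps(blob, indent=2))
    return outdir / "arousal_estimates.csv"
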