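"""Latent cognitive performance estimation from n-back behavior.

The performance state z_k evolves as a first-order autoregression

    z_{k+1} = rho * z_k + w_k,          w_k ~ N(0, sigma_w^2),

and is observed through two channels per trial: a binary correctness flag

    m_k ~ Bernoulli(p_k),   p_k = 1 / (1 + exp(-(z_k + mu))),

and a log-normal reaction time

    I_k = log t_k = alpha0 + alpha1 * z_k + delta_k,  delta_k ~ N(0, sigma_d^2).

The offset mu is held fixed at the logit of the empirical correct rate p0 so
the state is identified as a deviation from average performance.  Filtering
uses the standard Gaussian-approximate recursion with an implicit mean update
(the Bernoulli innovation is evaluated at the posterior mode) solved by
Newton–Raphson; smoothing is the fixed-interval recursion; parameters are
learned by EM with closed-form M-steps.
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
    "BehavioralSeries",
    "PerformanceParams",
    "filter_forward",
    "smooth_backward",
    "maximize_q2",
    "fit_em",
    "q2_value",
    "grid_posterior_oracle",
    "read_behavior_csv",
    "write_estimates",
]


@dataclass
class BehavioralSeries:
    """Per-trial binary responses and reaction times with task/session labels.

    ``t`` may contain NaN where no key press was recorded; such trials keep
    their (incorrect) binary observation but skip the continuous update.
    """

    m: np.ndarray
    t: np.ndarray
    task: np.ndarray | None = None
    session: np.ndarray | None = None

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        if self.m.shape != self.t.shape:
            raise ValueError("responses and reaction times must align")
        if not np.isin(self.m, (0, 1)).all():
            raise ValueError("responses must be binary")
        obs = np.isfinite(self.t)
        if np.any(self.t[obs] <= 0):
            raise ValueError("reaction times must be positive")
        for lab in ("task", "session"):
            v = getattr(self, lab)
            if v is not None and len(v) != self.m.size:
                raise ValueError(f"{lab} labels must align with trials")

    def __len__(self) -> int:
        return self.m.size

    @property
    def log_rt(self) -> np.ndarray:
        return np.log(self.t)

    def empirical_p0(self) -> float:
        """Mean correct rate, clipped away from {0,1} for a finite offset."""
        K = len(self)
        return float(np.clip(self.m.mean(), 1.0 / (2 * K), 1 - 1.0 / (2 * K)))


@dataclass
class PerformanceParams:
    rho: float = 0.95
    sigma_w2: float = 0.05
    alpha0: float = 0.0
    alpha1: float = -0.1
    sigma_delta2: float = 0.04
    p0: float = 0.5

    def __post_init__(self):
        if self.sigma_w2 <= 0 or self.sigma_delta2 <= 0:
            raise ValueError("noise variances must be strictly positive")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("baseline correct probability must be in (0, 1)")

    @property
    def mu(self) -> float:
        return baseline_offset(self.p0)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.rho, self.sigma_w2, self.alpha0, self.alpha1, self.sigma_delta2]
        )


def filter_forward(
    series: BehavioralSeries,
    params: PerformanceParams,
    z0: float = 0.0,
    s0: float | None = None,
):
    """Forward filter; returns (estimate, pred_mean, pred_var).

    Prediction: z_{k|k-1} = rho z_{k-1|k-1}, s2_{k|k-1} = rho^2 s2 + sigma_w^2.
    Update: implicit mean equation solved by Newton–Raphson; posterior
    variance adds the Bernoulli and Gaussian precisions, so it never exceeds
    the predicted variance.  Trials with missing reaction time use the
    binary-only update.
    """
    if len(series) == 0:
        raise ValueError("empty behavioral series")
    K = len(series)
    mu = params.mu
    rho, sw2 = params.rho, params.sigma_w2
    a0, a1, sd2 = params.alpha0, params.alpha1, params.sigma_delta2
    if s0 is None:
        s0 = sw2

    fm = np.empty(K)
    fv = np.empty(K)
    pm = np.empty(K)
    pv = np.empty(K)
    I = series.log_rt
    has_rt = np.isfinite(I)
    z, s2 = z0, s0
    for k in range(K):
        zp = rho * z
        sp = rho**2 * s2 + sw2
        pm[k], pv[k] = zp, sp
        if has_rt[k]:
            gain = sp / (a1**2 * sp + sd2)
            c1 = gain * sd2
            c0 = gain * a1 * (I[k] - a0 - a1 * zp)
            z = solve_implicit_update(zp, c0, c1, series.m[k], mu)
            p = sigmoid_probability(z, mu)
            s2 = 1.0 / (1.0 / sp + p * (1 - p) + a1**2 / sd2)
        else:
            z = solve_implicit_update(zp, 0.0, sp, series.m[k], mu)
            p = sigmoid_probability(z, mu)
            s2 = 1.0 / (1.0 / sp + p * (1 - p))
        fm[k], fv[k] = z, s2
    est = LatentStateEstimate(mean=fm, variance=fv, offset=mu)
    return est, pm, pv


def smooth_backward(filtered, pred_mean, pred_var, params: PerformanceParams):
    """Fixed-interval smoother; returns (estimate, gains B_k)."""
    sm, sv, B = smooth_backward_gaussian(
        filtered.mean, filtered.variance, pred_mean, pred_var, params.rho
    )
    return LatentStateEstimate(mean=sm, variance=sv, offset=params.mu), B


def maximize_q2(
    series: BehavioralSeries,
    ez: np.ndarray,
    ez2: np.ndarray,
    ezz: np.ndarray,
    params: PerformanceParams,
    z0: float = 0.0,
) -> PerformanceParams:
    """Closed-form M-step for {alpha0, alpha1, sigma_d^2, rho, sigma_w^2}.

    The regression coefficients come from the normal equations in the E-step
    moments; the variances are averaged expected squared residuals; the AR
    coefficient is the expected lag-1 regression through the origin.  ``mu``
    is not re-estimated (held at the empirical baseline).
    """
    I = series.log_rt
    has_rt = np.isfinite(I)
    K = len(series)
    Io, ezo, ez2o = I[has_rt], ez[has_rt], ez2[has_rt]
    n_obs = int(has_rt.sum())
    A = np.array([[n_obs, ezo.sum()], [ezo.sum(), ez2o.sum()]])
    b = np.array([Io.sum(), (Io * ezo).sum()])
    if abs(np.linalg.det(A)) < 1e-12 * max(1.0, ez2o.sum()) ** 2:
        raise np.linalg.LinAlgError("degenerate normal equations for (a0, a1)")
    alpha0, alpha1 = np.linalg.solve(A, b)
    resid2 = (
        Io**2
        - 2 * Io * (alpha0 + alpha1 * ezo)
        + alpha0**2
        + 2 * alpha0 * alpha1 * ezo
        + alpha1**2 * ez2o
    )
    sigma_delta2 = float(np.maximum(resid2.mean(), 0.0))
    if sigma_delta2 == 0.0:
        log.warning("degenerate continuous channel: zero residual variance")
        sigma_delta2 = 1e-12

    # rho from sum E[z_k z_{k-1}] / sum E[z_{k-1}^2] (z_0 = z0 point mass)
    num = z0 * ez[0] + ezz.sum()
    den = z0**2 + ez2[:-1].sum()
    rho = float(num / den)
    if abs(rho) >= 1.0:
        log.warning("unconstrained AR estimate |rho| >= 1 (%.4f)", rho)
    # sigma_w^2 from mean expected squared innovation under the new rho
    e_prev2 = np.concatenate([[z0**2], ez2[:-1]])
    e_cross = np.concatenate([[z0 * ez[0]], ezz])
    sigma_w2 = float((ez2 - 2 * rho * e_cross + rho**2 * e_prev2).mean())
    if sigma_w2 <= 0:
        log.warning("degenerate process noise estimate; flooring")
        sigma_w2 = 1e-12
    return replace(
        params,
        rho=rho,
        sigma_w2=sigma_w2,
        alpha0=float(alpha0),
        alpha1=float(alpha1),
        sigma_delta2=sigma_delta2,
    )


def q2_value(
    series: BehavioralSeries,
    ez: np.ndarray,
    ez2: np.ndarray,
    ezz: np.ndarray,
    sv: np.ndarray,
    params: PerformanceParams,
    z0: float = 0.0,
) -> float:
    """Expected complete-data log-likelihood Q2 at ``params``.

    The Bernoulli term E[m(mu+z) - log(1+e^{mu+z})] has no closed form; it is
    evaluated by a second-order expansion around the smoothed mean (the
    curvature term subtracts p(1-p)/2 times the smoothed variance).
    """
    mu = params.mu
    p = sigmoid_probability(ez, mu)
    bern = series.m * (mu + ez) - np.logaddexp(0.0, mu + ez) - 0.5 * sv * p * (1 - p)
    I = series.log_rt
    has_rt = np.isfinite(I)
    Io, ezo, ez2o = I[has_rt], ez[has_rt], ez2[has_rt]
    a0, a1, sd2 = params.alpha0, params.alpha1, params.sigma_delta2
    resid2 = (
        Io**2
        - 2 * Io * (a0 + a1 * ezo)
        + a0**2
        + 2 * a0 * a1 * ezo
        + a1**2 * ez2o
    )
    cont = -0.5 * has_rt.sum() * np.log(2 * np.pi * sd2) - resid2.sum() / (2 * sd2)
    rho, sw2 = params.rho, params.sigma_w2
    e_prev2 = np.concatenate([[z0**2], ez2[:-1]])
    e_cross = np.concatenate([[z0 * ez[0]], ezz])
    innov2 = ez2 - 2 * rho * e_cross + rho**2 * e_prev2
    proc = -0.5 * len(series) * np.log(2 * np.pi * sw2) - innov2.sum() / (2 * sw2)
    return float(bern.sum() + cont + proc)


def _initial_params(series: BehavioralSeries) -> PerformanceParams:
    I = series.log_rt
    Io = I[np.isfinite(I)]
    var_I = float(np.var(Io)) if Io.size > 1 else 0.1
    return PerformanceParams(
        rho=0.95,
        sigma_w2=max(var_I / 2, 1e-3),
        alpha0=float(Io.mean()) if Io.size else 0.0,
        alpha1=-0.1,
        sigma_delta2=max(var_I / 2, 1e-3),
        p0=series.empirical_p0(),
    )


def fit_em(
    series: BehavioralSeries,
    init: PerformanceParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
):
    """EM fit; returns (params, smoothed estimate, diagnostics).

    Alternates forward filter + smoother + moments (E-step) with the
    closed-form M-step until the max relative parameter change drops below
    ``tol``.  The recorded Q2 trajectory is the maximized value per iteration.
    """
    if len(series) < 10:
        raise ValueError("EM needs at least 10 trials")
    params = init if init is not None else _initial_params(series)
    params = replace(params, p0=series.empirical_p0())
    q_traj = []
    q_gain = []
    converged = False
    delta = np.inf
    smoothed = None
    for it in range(1, max_iter + 1):
        filtered, pm, pv = filter_forward(series, params)
        smoothed, B = smooth_backward(filtered, pm, pv, params)
        ez = smoothed.mean
        ez2, ezz = posterior_moments(ez, smoothed.variance, B)
        new = maximize_q2(series, ez, ez2, ezz, params)
        if not np.all(np.isfinite(new.as_array())):
            raise FloatingPointError(f"EM diverged at iteration {it}")
        q_new = q2_value(series, ez, ez2, ezz, smoothed.variance, new)
        q_old = q2_value(series, ez, ez2, ezz, smoothed.variance, params)
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
    series: BehavioralSeries,
    params: PerformanceParams,
    z0: float = 0.0,
    s0: float | None = None,
    n_points: int = 2001,
):
    """Exact filtered/smoothed posterior by dense-grid quadrature (K <= 12).

    Independent numerical check of the Gaussian-approximate recursions; not
    part of the estimation path.
    """
    if len(series) > 12:
        raise ValueError("grid oracle is restricted to short series")
    mu = params.mu
    I = series.log_rt
    if s0 is None:
        s0 = params.sigma_w2

    def loglik(k, grid):
        p = sigmoid_probability(grid, mu)
        ll = np.where(series.m[k] == 1, np.log(p), np.log1p(-p))
        if np.isfinite(I[k]):
            r = I[k] - params.alpha0 - params.alpha1 * grid
            ll = ll - 0.5 * r**2 / params.sigma_delta2
        return ll

    return grid_posterior(
        loglik, len(series), params.rho, params.sigma_w2, z0, s0, n_points=n_points
    )


def read_behavior_csv(path) -> BehavioralSeries:
    """Read a behavior table ``trial,task,session,response,rt_s``."""
    df = pd.read_csv(path)
    return BehavioralSeries(
        m=df["response"].to_numpy(),
        t=df["rt_s"].to_numpy(),
        task=df["task"].to_numpy() if "task" in df else None,
        session=df["session"].to_numpy() if "session" in df else None,
    )


def write_estimates(outdir, smoothed: LatentStateEstimate, params: PerformanceParams):
    """Write per-trial estimates CSV and a parameters JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "trial": np.arange(1, len(smoothed) + 1),
            "z_mean": smoothed.mean,
            "z_var": smoothed.variance,
            "p": smoothed.prob,
            "p_low": smoothed.ci_low,
            "p_high": smoothed.ci_high,
        }
    ).to_csv(outdir / "performance_estimates.csv", index=False)
    blob = {
        "rho": params.rho,
        "sigma_w2": params.sigma_w2,
        "alpha0": params.alpha0,
        "alpha1": params.alpha1,
        "sigma_delta2": params.sigma_delta2,
        "p0": params.p0,
        "mu": params.mu,
    }
    (outdir / "performance_params.json").write_text(json.dumps(blob, indent=2))
    return outdir / "performance_estimates.csv"
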