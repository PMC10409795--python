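"""Synthetic behavioral, electrodermal, and EEG session generator.

Generates data with exactly the generative structure the estimators assume —
an AR(1) performance walk emitting Bernoulli correctness and log-normal
reaction times, a random-walk arousal state emitting a marked impulse train,
skin conductance built by the phasic-kernel/tonic-spline forward model (the
same design matrices the deconvolution uses), and band-structured EEG noise —
and writes the streams in the wearable-device export dialects so the whole
pipeline runs with no recorded data.

Default parameter values are chosen to give realistic n-back correct rates
(~70–90%) and sparse electrodermal impulses; every draw flows from one
explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .arousal import ImpulseSeries
from .deconvolution import (
    PhasicKernelParams,
    SkinConductanceTrace,
    TonicBasis,
    build_design_matrices,
)
from .eeg import CHANNELS, EEGRecording
from .performance import BehavioralSeries

__all__ = [
    "SessionSchedule",
    "PerformanceTruth",
    "ArousalTruth",
    "simulate_performance_trajectory",
    "simulate_arousal_impulses",
    "simulate_sparse_impulse_train",
    "synthesize_scr_trace",
    "synthesize_eeg",
    "generate_session_bundle",
    "write_session_bundle",
]

BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}


@dataclass(frozen=True)
class SessionSchedule:
    """Timing of an n-back recording session block.

    Each session holds ``n_trials_per_session`` trials of
    ``stimuli_per_trial`` stimulus+response pairs preceded by an instruction
    and followed by a break, with a final relaxation period; sessions are
    separated by rest intervals.  With the defaults one session lasts
    16*(5 + 22*2 + 10) + 20 = 964 s.
    """

    n_trials_per_session: int = 16
    stimuli_per_trial: int = 22
    instruction_s: float = 5.0
    stimulus_s: float = 0.5
    response_s: float = 1.5
    inter_trial_break_s: float = 10.0
    final_relax_s: float = 20.0
    sessions: tuple = (
        ("baseline", 30.0),
        ("relaxing", 30.0),
        ("exciting", 30.0),
        ("generated", 30.0),
    )  # (label, rest seconds before the session)

    def __post_init__(self):
        durations = (
            self.instruction_s,
            self.stimulus_s,
            self.response_s,
            self.inter_trial_break_s,
            self.final_relax_s,
        )
        if any(d <= 0 for d in durations):
            raise ValueError("all schedule durations must be positive")
        if self.n_trials_per_session < 1 or self.stimuli_per_trial < 1:
            raise ValueError("schedule needs at least one trial and stimulus")
        if not self.sessions:
            raise ValueError("schedule needs at least one session")

    @property
    def trial_block_s(self) -> float:
        return (
            self.instruction_s
            + self.stimuli_per_trial * (self.stimulus_s + self.response_s)
            + self.inter_trial_break_s
        )

    @property
    def session_duration_s(self) -> float:
        return self.n_trials_per_session * self.trial_block_s + self.final_relax_s

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def total_trials(self) -> int:
        return self.n_sessions * self.n_trials_per_session

    @property
    def total_duration_s(self) -> float:
        return sum(rest for _, rest in self.sessions) + (
            self.n_sessions * self.session_duration_s
        )

    def session_intervals(self):
        """Half-open (label, start_s, end_s) spans of the task sessions."""
        out = []
        t = 0.0
        for label, rest in self.sessions:
            t += rest
            out.append((label, t, t + self.session_duration_s))
            t += self.session_duration_s
        return out

    def trial_table(self) -> pd.DataFrame:
        """Per-trial onset times, task level (alternating 1/3-back), session."""
        rows = []
        trial = 0
        for label, start, _ in self.session_intervals():
            for i in range(self.n_trials_per_session):
                trial += 1
                rows.append(
                    {
                        "trial": trial,
                        "task": "1-back" if i % 2 == 0 else "3-back",
                        "session": label,
                        "onset_s": start + i * self.trial_block_s + self.instruction_s,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PerformanceTruth:
    z: np.ndarray
    params: dict
    seed: int


@dataclass
class ArousalTruth:
    x: np.ndarray
    params: dict
    seed: int
    t_grid: float = 0.25


def simulate_performance_trajectory(
    schedule: SessionSchedule,
    seed: int,
    rho: float = 0.98,
    sigma_w2: float = 0.05,
    alpha0: float = 0.0,
    alpha1: float = -0.3,
    sigma_delta2: float = 0.04,
    mu: float = 1.0,
    z0: float = 0.0,
    session_shift: dict | None = None,
):
    """Latent performance walk with Bernoulli + log-normal observations.

    ``session_shift`` optionally adds a per-session offset to the latent
    state before emission (stepped session means for ordering checks).
    Variances of zero give the noise-free generative limit.
    """
    if sigma_w2 < 0 or sigma_delta2 < 0:
        raise ValueError("variances must be nonnegative")
    table = schedule.trial_table()
    K = len(table)
    rng = np.random.default_rng(seed)
    z = np.empty(K)
    prev = z0
    for k in range(K):
        prev = rho * prev + rng.normal(0.0, np.sqrt(sigma_w2))
        z[k] = prev
    z_emit = z.copy()
    if session_shift:
        z_emit += table["session"].map(session_shift).fillna(0.0).to_numpy()
    p = 1.0 / (1.0 + np.exp(-(z_emit + mu)))
    m = rng.binomial(1, p)
    t = np.exp(alpha0 + alpha1 * z_emit + rng.normal(0.0, np.sqrt(sigma_delta2), K))
    truth = PerformanceTruth(
        z=z_emit,
        params=dict(
            rho=rho, sigma_w2=sigma_w2, alpha0=alpha0, alpha1=alpha1,
            sigma_delta2=sigma_delta2, mu=mu,
        ),
        seed=seed,
    )
    series = BehavioralSeries(
        m=m,
        t=t,
        task=table["task"].to_numpy(),
        session=table["session"].to_numpy(),
    )
    return truth, series


def simulate_arousal_impulses(
    n_steps: int,
    seed: int,
    sigma_eps2: float = 0.01,
    gamma0: float = 0.3,
    gamma1: float = 0.5,
    sigma_v2: float = 0.01,
    beta: float = -2.0,
    x0: float = 0.0,
    t_grid: float = 0.25,
):
    """Random-walk arousal state emitting a marked Bernoulli impulse train."""
    if n_steps < 1:
        raise ValueError("need at least one step")
    if sigma_eps2 < 0 or sigma_v2 < 0:
        raise ValueError("variances must be nonnegative")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(sigma_eps2), n_steps)
    x = x0 + np.cumsum(steps)
    with np.errstate(over="ignore"):
        a = 1.0 / (1.0 + np.exp(-(x + beta)))
    n = rng.binomial(1, a)
    r = np.full(n_steps, np.nan)
    on = n == 1
    r[on] = gamma0 + gamma1 * x[on] + rng.normal(0.0, np.sqrt(sigma_v2), int(on.sum()))
    truth = ArousalTruth(
        x=x,
        params=dict(
            sigma_eps2=sigma_eps2, gamma0=gamma0, gamma1=gamma1,
            sigma_v2=sigma_v2, beta=beta,
        ),
        seed=seed,
        t_grid=t_grid,
    )
    return truth, ImpulseSeries(n=n, r=r, t_grid=t_grid)


def simulate_sparse_impulse_train(
    seed: int,
    n_steps: int = 800,
    t_grid: float = 0.25,
    min_gap_s: float = 10.0,
    amp_range: tuple = (0.1, 0.5),
):
    """Well-separated random impulse train for deconvolution benchmarks.

    Events are placed at least ``min_gap_s`` apart (plus a random extra gap
    of up to the same length) with uniform amplitudes.  Returns
    (ImpulseSeries, locations, amplitudes).
    """
    rng = np.random.default_rng(seed)
    gap = int(round(min_gap_s / t_grid))
    locs, t = [], int(rng.integers(20, 60))
    while t < n_steps - 20:
        locs.append(t)
        t += gap + int(rng.integers(0, gap))
    amps = rng.uniform(*amp_range, len(locs))
    n = np.zeros(n_steps, dtype=int)
    r = np.full(n_steps, np.nan)
    for loc, a in zip(locs, amps):
        n[loc] = 1
        r[loc] = a
    return ImpulseSeries(n=n, r=r, t_grid=t_grid), np.array(locs), amps


def synthesize_scr_trace(
    impulses: ImpulseSeries,
    kernel: PhasicKernelParams = PhasicKernelParams(),
    tonic_coeffs: np.ndarray | float = 1.5,
    y_p0: float = 0.0,
    noise_sd: float = 0.01,
    t_y: float = 0.25,
    seed: int = 0,
    basis: TonicBasis = TonicBasis(),
    amplitude_floor: float = 0.01,
) -> SkinConductanceTrace:
    """Forward-model skin conductance from a marked impulse train.

    Uses the deconvolution module's own design matrices, so with
    ``noise_sd=0`` the trace is exactly H0*y_p0 + H1 u + H2 q.  Negative
    marks (possible under the Gaussian mark model) are floored at
    ``amplitude_floor`` since conductance responses are nonnegative.  A
    scalar ``tonic_coeffs`` means a flat tonic at that level (B-spline
    partition of unity).
    """
    t_u = impulses.t_grid
    N = len(impulses)
    M = int(round(N * t_u / t_y))
    H0, H1, H2 = build_design_matrices(kernel, t_y, t_u, M, N, basis)
    u = np.where(impulses.n == 1, np.maximum(impulses.r, amplitude_floor), 0.0)
    if np.isscalar(tonic_coeffs):
        q = np.full(H2.shape[1], float(tonic_coeffs))
    else:
        q = np.asarray(tonic_coeffs, float)
        if q.size != H2.shape[1]:
            raise ValueError(
                f"tonic basis needs {H2.shape[1]} coefficients, got {q.size}"
            )
    y = H0 * y_p0 + H1 @ u + H2 @ q
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, M)
    return SkinConductanceTrace(y=y, t_y=t_y)


def synthesize_eeg(
    band_amplitudes,
    schedule: SessionSchedule,
    fs: float = 256.0,
    seed: int = 0,
    broadband_sd: float = 1.0,
) -> EEGRecording:
    """Band-structured Gaussian EEG with per-session band amplitudes.

    ``band_amplitudes`` maps session label -> {band -> amplitude}, where a
    band is a name from delta/theta/alpha/beta/gamma or a (lo, hi) tuple in
    Hz.  Each channel is broadband Gaussian noise plus unit-variance
    band-limited noise scaled by a per-session amplitude envelope, so
    measured band power scales with amplitude squared.
    """
    n = int(round(schedule.total_duration_s * fs))
    rng = np.random.default_rng(seed)
    intervals = schedule.session_intervals()
    t = np.arange(n) / fs

    bands = set()
    for amps in band_amplitudes.values():
        bands.update(amps.keys())
    resolved = {}
    for b in bands:
        lo, hi = BAND_EDGES[b] if isinstance(b, str) else b
        if not 0 < lo < hi < fs / 2:
            raise ValueError(f"band {b} outside (0, Nyquist)")
        resolved[b] = (lo, hi)

    samples = rng.normal(0.0, broadband_sd, (len(CHANNELS), n))
    for b, (lo, hi) in resolved.items():
        env = np.zeros(n)
        for label, start, end in intervals:
            amp = band_amplitudes.get(label, {}).get(b, 0.0)
            env[(t >= start) & (t < end)] = amp
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        for c in range(len(CHANNELS)):
            comp = sps.sosfilt(sos, rng.normal(0.0, 1.0, n))
            sd = comp.std()
            if sd > 0:
                comp /= sd
            samples[c] += env * comp
    return EEGRecording(samples=samples, fs=fs)


def generate_session_bundle(
    schedule: SessionSchedule | None = None,
    seed: int = 0,
    t_u: float = 0.25,
    eda_hz: float = 4.0,
    eeg_fs: float = 256.0,
    noise_sd: float = 0.01,
    beta_amplitudes: dict | None = None,
    performance_kwargs: dict | None = None,
    arousal_kwargs: dict | None = None,
):
    """Simulate one full multi-session recording.

    Returns a dict with the behavioral series, skin conductance trace, EEG
    recording, annotation intervals, schedule, and both latent ground truths.
    Child seeds are spawned deterministically from ``seed``.
    """
    schedule = schedule or SessionSchedule()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    perf_truth, behavior = simulate_performance_trajectory(
        schedule, seeds[0], **(performance_kwargs or {})
    )
    D = schedule.total_duration_s
    J = int(round(D / t_u))
    ar_truth, impulses = simulate_arousal_impulses(
        J, seeds[1], t_grid=t_u, **(arousal_kwargs or {})
    )
    eda = synthesize_scr_trace(
        impulses, noise_sd=noise_sd, t_y=1.0 / eda_hz, seed=seeds[2]
    )
    if beta_amplitudes is None:
        levels = [1.0, 1.3, 1.25, 1.45]
        beta_amplitudes = {
            label: {"beta": levels[i % len(levels)], "alpha": 0.8}
            for i, (label, _) in enumerate(schedule.sessions)
        }
    eeg = synthesize_eeg(beta_amplitudes, schedule, fs=eeg_fs, seed=seeds[3])
    annotations = schedule.session_intervals()
    return {
        "schedule": schedule,
        "behavior": behavior,
        "eda": eda,
        "eeg": eeg,
        "impulses": impulses,
        "annotations": annotations,
        "performance_truth": perf_truth,
        "arousal_truth": ar_truth,
        "seed": seed,
    }


def _write_e4_csv(path, start_time, rate, values):
    values = np.atleast_2d(values)
    if values.shape[0] > values.shape[1]:
        values = values.T
    n_cols = values.shape[0]
    with open(path, "w") as fh:
        fh.write(",".join([f"{start_time:.2f}"] * n_cols) + "\n")
        fh.write(",".join([f"{float(rate):.6f}"] * n_cols) + "\n")
        np.savetxt(fh, values.T, delimiter=",", fmt="%.6f")


def write_session_bundle(dir_path, bundle: dict, start_time: float = 1_600_000_000.0):
    """Write a simulated bundle in the device-export dialects.

    Emits EDA/BVP/TEMP/ACC/HR/tags CSVs (wristband dialect: row 1 start
    epoch, row 2 sample rate), the headband EEG CSV, behavior and annotation
    tables, and ground-truth sidecars for parameter-recovery tests.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    schedule: SessionSchedule = bundle["schedule"]
    eda: SkinConductanceTrace = bundle["eda"]
    eeg: EEGRecording = bundle["eeg"]
    D = schedule.total_duration_s
    rng = np.random.default_rng(bundle["seed"] + 1)

    _write_e4_csv(d / "EDA.csv", start_time, 1.0 / eda.t_y, eda.y)
    _write_e4_csv(d / "BVP.csv", start_time, 64, rng.normal(0, 1, int(D * 64)))
    _write_e4_csv(d / "TEMP.csv", start_time, 4, 33 + rng.normal(0, 0.1, int(D * 4)))
    _write_e4_csv(
        d / "ACC.csv", start_time, 32,
        rng.integers(-64, 64, (int(D * 32), 3)).astype(float),
    )
    _write_e4_csv(d / "HR.csv", start_time, 1, 70 + rng.normal(0, 2, int(D)))
    with open(d / "tags.csv", "w") as fh:
        for _, s, _e in schedule.session_intervals():
            fh.write(f"{start_time + s:.2f}\n")

    ts = start_time + np.arange(eeg.n_samples) / eeg.fs
    eeg_df = pd.DataFrame({"timestamp": ts})
    for i, ch in enumerate(eeg.channels):
        eeg_df[ch] = eeg.samples[i]
    eeg_df.to_csv(d / "eeg.csv", index=False, float_format="%.5f")

    behavior: BehavioralSeries = bundle["behavior"]
    table = schedule.trial_table()
    pd.DataFrame(
        {
            "trial": table["trial"],
            "task": behavior.task,
            "session": behavior.session,
            "response": behavior.m,
            "rt_s": behavior.t,
            "onset_s": table["onset_s"],
        }
    ).to_csv(d / "behavior.csv", index=False)
    pd.DataFrame(
        bundle["annotations"], columns=["label", "start_s", "end_s"]
    ).to_csv(d / "annotations.csv", index=False)

    pt: PerformanceTruth = bundle["performance_truth"]
    pd.DataFrame({"trial": np.arange(1, pt.z.size + 1), "z": pt.z}).to_csv(
        d / "performance_truth.csv", index=False
    )
    at: ArousalTruth = bundle["arousal_truth"]
    imp: ImpulseSeries = bundle["impulses"]
    pd.DataFrame(
        {"time_s": imp.times, "x": at.x, "n": imp.n, "r": imp.r}
    ).to_csv(d / "arousal_truth.csv", index=False)
    return d
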