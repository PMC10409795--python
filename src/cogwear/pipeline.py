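"""Session-level orchestration: I/O, alignment, summaries, relationships.

Reads a multi-stream recording (wristband physiology, headband EEG, n-back
behavior, labeled session intervals), runs the estimators — performance EM on
the behavioral series, deconvolution + arousal EM on skin conductance,
beta-band power on EEG — and produces per-session summaries, the
arousal–performance inverted-U and beta–performance linear fits, and one-way
ANOVA comparisons.  All interval logic is half-open [start, end) in seconds
from recording start.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import arousal as arousal_mod
from . import deconvolution as deconv_mod
from . import eeg as eeg_mod
from . import performance as perf_mod
from .deconvolution import DeconvolutionConfig, SkinConductanceTrace
from .eeg import BETA_BAND, EEGRecording
from .performance import BehavioralSeries

log = logging.getLogger(__name__)

__all__ = [
    "SessionBundle",
    "SessionSummary",
    "read_e4_bundle",
    "read_session_bundle",
    "align_streams",
    "summarize_sessions",
    "percent_change",
    "fit_inverted_u",
    "fit_linear_relation",
    "anova_oneway",
    "run_pipeline",
]


@dataclass
class SessionBundle:
    """Aligned multi-stream recording with labeled session intervals."""

    behavior: BehavioralSeries
    trial_onsets: np.ndarray
    eda: SkinConductanceTrace
    eeg: EEGRecording | None
    annotations: list  # (label, start_s, end_s), half-open, ordered
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ann = sorted(self.annotations, key=lambda a: a[1])
        for (l1, s1, e1), (l2, s2, e2) in zip(ann, ann[1:]):
            if e1 > s2:
                raise ValueError(f"annotations {l1!r} and {l2!r} overlap")
        for label, s, e in ann:
            if e <= s:
                raise ValueError(f"annotation {label!r} is empty or reversed")
        self.annotations = ann


@dataclass
class SessionSummary:
    session: str
    task: str
    n_trials: int
    correct_pct: float
    mean_rt: float
    mean_perf: float
    mean_arousal: float
    beta_power: float = np.nan
    flagged: bool = False


def read_e4_bundle(dir_path) -> dict:
    """Read the wristband export directory (EDA required, others optional).

    Each file carries its start epoch in row 1 and sample rate in row 2;
    timestamps are reconstructed as start + k/rate.  Returns a dict of
    streams keyed by signal name; ACC maps to three aligned component
    series.
    """
    d = Path(dir_path)
    if not (d / "EDA.csv").exists():
        raise FileNotFoundError(f"{d}: EDA.csv is required")
    out = {}
    for name in ("EDA", "BVP", "TEMP", "ACC", "HR"):
        path = d / f"{name}.csv"
        if not path.exists():
            log.info("optional stream %s missing; skipped", path.name)
            continue
        raw = pd.read_csv(path, header=None).to_numpy(float)
        if raw.shape[0] < 3:
            raise ValueError(f"{path}: malformed wristband export (too few rows)")
        start, rate = float(raw[0, 0]), float(raw[1, 0])
        if rate <= 0 or not np.isfinite(start):
            raise ValueError(f"{path}: malformed header rows")
        values = raw[2:]
        out[name] = {
            "start_time": start,
            "rate": rate,
            "values": values if values.shape[1] > 1 else values.ravel(),
        }
    tags = d / "tags.csv"
    if tags.exists():
        txt = tags.read_text().split()
        out["tags"] = np.array([float(v) for v in txt])
    return out


def read_session_bundle(dir_path) -> SessionBundle:
    """Read a full session directory written by the synthetic generator."""
    d = Path(dir_path)
    streams = read_e4_bundle(d)
    eda_raw = streams["EDA"]
    eda = SkinConductanceTrace(
        y=eda_raw["values"],
        t_y=1.0 / eda_raw["rate"],
        start_time=eda_raw["start_time"],
    )
    beh = pd.read_csv(d / "behavior.csv")
    behavior = BehavioralSeries(
        m=beh["response"].to_numpy(),
        t=beh["rt_s"].to_numpy(),
        task=beh["task"].to_numpy(),
        session=beh["session"].to_numpy(),
    )
    onsets = beh["onset_s"].to_numpy(float) if "onset_s" in beh else np.array([])
    ann = [
        (r.label, float(r.start_s), float(r.end_s))
        for r in pd.read_csv(d / "annotations.csv").itertuples()
    ]
    eeg = eeg_mod.read_eeg_csv(d / "eeg.csv") if (d / "eeg.csv").exists() else None
    return SessionBundle(
        behavior=behavior,
        trial_onsets=onsets,
        eda=eda,
        eeg=eeg,
        annotations=ann,
        metadata={"dir": str(d)},
    )


def _slice_half_open(times: np.ndarray, start: float, end: float) -> np.ndarray:
    return np.flatnonzero((times >= start) & (times < end))


def align_streams(bundle: SessionBundle) -> dict:
    """Slice every stream by the half-open annotation intervals.

    Returns {label: {"eda": sample indices, "trials": trial indices,
    "interval": (start, end)}}.  Empty intersections yield empty index
    arrays; an annotation outside the recording span raises.
    """
    eda_times = np.arange(len(bundle.eda)) * bundle.eda.t_y
    span_end = len(bundle.eda) * bundle.eda.t_y
    out = {}
    for label, start, end in bundle.annotations:
        if start < 0 or start >= span_end:
            raise ValueError(
                f"annotation {label!r} [{start}, {end}) outside recording span"
            )
        out[label] = {
            "interval": (start, end),
            "eda": _slice_half_open(eda_times, start, end),
            "trials": _slice_half_open(bundle.trial_onsets, start, end),
        }
    return out


def summarize_sessions(
    bundle: SessionBundle,
    perf_est,
    arousal_est=None,
    arousal_times: np.ndarray | None = None,
    beta_by_session: dict | None = None,
) -> list:
    """Per session x task cell: correct %, mean RT, mean latent states.

    Cells with no trials are returned flagged rather than dropped.
    """
    segs = align_streams(bundle)
    beh = bundle.behavior
    out = []
    for label in segs:
        tri = segs[label]["trials"]
        start, end = segs[label]["interval"]
        tasks = (
            np.unique(beh.task[tri]) if (beh.task is not None and tri.size) else ["all"]
        )
        for task in tasks:
            if beh.task is not None and tri.size:
                sel = tri[beh.task[tri] == task]
            else:
                sel = tri
            if sel.size == 0:
                out.append(
                    SessionSummary(label, str(task), 0, np.nan, np.nan, np.nan,
                                   np.nan, flagged=True)
                )
                continue
            rts = beh.t[sel]
            rts = rts[np.isfinite(rts)]
            if arousal_est is not None and arousal_times is not None:
                a_idx = _slice_half_open(arousal_times, start, end)
                mean_ar = float(arousal_est.mean[a_idx].mean()) if a_idx.size else np.nan
            else:
                mean_ar = np.nan
            out.append(
                SessionSummary(
                    session=label,
                    task=str(task),
                    n_trials=int(sel.size),
                    correct_pct=float(100.0 * beh.m[sel].mean()),
                    mean_rt=float(rts.mean()) if rts.size else np.nan,
                    mean_perf=float(perf_est.mean[sel].mean()),
                    mean_arousal=mean_ar,
                    beta_power=(beta_by_session or {}).get(label, np.nan),
                )
            )
    return out


def percent_change(baseline: float, actuated: float) -> float:
    """100 * (actuated - baseline) / baseline; NaN (logged) at zero baseline."""
    if baseline == 0:
        log.warning("percent change undefined for zero baseline")
        return float("nan")
    return 100.0 * (actuated - baseline) / baseline


@dataclass
class QuadraticFit:
    c0: float
    c1: float
    c2: float
    concave: bool
    vertex: float | None


def minmax_normalize(v: np.ndarray) -> np.ndarray:
    """Min–max rescale to [0, 1]; constant input raises."""
    v = np.asarray(v, float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi <= lo:
        raise ValueError("cannot min-max normalize a constant series")
    return (v - lo) / (hi - lo)


def fit_inverted_u(x: np.ndarray, y: np.ndarray) -> QuadraticFit:
    """Least-squares quadratic y = c0 + c1 x + c2 x^2 with concavity check.

    Inputs are expected min–max normalized to [0, 1].  The Yerkes–Dodson
    inverted-U shows as c2 < 0 with an interior vertex -c1/(2 c2).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 5:
        raise ValueError("need at least 5 points for the quadratic fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x for quadratic fit")
    c2, c1, c0 = np.polyfit(x, y, 2)
    # numerically-zero curvature (e.g. exactly collinear points) is not concave
    tol = 1e-8 * max(1.0, abs(c0), abs(c1))
    concave = c2 < -tol
    vertex = float(-c1 / (2 * c2)) if concave else None
    return QuadraticFit(float(c0), float(c1), float(c2), bool(concave), vertex)


def fit_linear_relation(x: np.ndarray, y: np.ndarray):
    """Ordinary least-squares line; returns (slope, intercept, r_value, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points for the linear fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x for linear fit")
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue, res.pvalue


def anova_oneway(groups) -> tuple:
    """Classical one-way ANOVA from the between/within decomposition.

    F = MSB/MSW with (k-1, N-k) degrees of freedom; p from the F
    distribution.  Zero within-variance with equal means is degenerate and
    returns (0, 1) with a warning.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    N = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, N - k
    if ssw == 0:
        if ssb == 0:
            log.warning("degenerate ANOVA: all values identical")
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    return float(F), p


def run_pipeline(config, output_dir=None) -> dict:
    """Execute the full analysis: read -> align -> deconvolve -> fit arousal
    -> fit performance -> EEG power -> summaries -> relationship fits ->
    ANOVA.  ``config`` is a YAML path or a dict; results are written to
    ``output_dir`` (CSV/JSON + log) and returned.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(output_dir or config.get("output_dir", "cogwear_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "report.log", mode="w")
    logging.getLogger("cogwear").addHandler(handler)

    stage = "read"
    try:
        if "input_dir" in config:
            bundle = read_session_bundle(config["input_dir"])
        elif "synthetic" in config:
            from .synthetic import SessionSchedule, generate_session_bundle

            syn = dict(config["synthetic"])
            sched_kwargs = syn.pop("schedule", {})
            if "sessions" in sched_kwargs:
                sched_kwargs["sessions"] = tuple(
                    (str(l), float(r)) for l, r in sched_kwargs["sessions"]
                )
            raw = generate_session_bundle(
                SessionSchedule(**sched_kwargs), **syn
            )
            table = raw["schedule"].trial_table()
            bundle = SessionBundle(
                behavior=raw["behavior"],
                trial_onsets=table["onset_s"].to_numpy(),
                eda=raw["eda"],
                eeg=raw["eeg"],
                annotations=raw["annotations"],
                metadata={"synthetic_seed": raw["seed"]},
            )
        else:
            raise ValueError("config must name input_dir or synthetic")

        stage = "fit-performance"
        tol = float(config.get("tol", 1e-4))
        max_iter = int(config.get("max_iter", 50))
        perf_params, perf_est, perf_diag = perf_mod.fit_em(
            bundle.behavior, tol=tol, max_iter=max_iter
        )
        perf_mod.write_estimates(outdir, perf_est, perf_params)

        stage = "deconvolve"
        dcfg = DeconvolutionConfig(
            block_s=float(config.get("block", 200.0)),
            stride_s=float(config.get("stride", 100.0)),
            trim_s=float(config.get("trim", 50.0)),
        )
        dres = deconv_mod.deconvolve_recording(bundle.eda, dcfg)
        deconv_mod.write_deconvolution(outdir, dres, bundle.eda.t_y)
        impulses = deconv_mod.impulses_to_marked_series(
            dres, threshold=float(config.get("threshold", 0.01))
        )

        stage = "fit-arousal"
        ar_params, ar_est, ar_diag = arousal_mod.fit_em(
            impulses, tol=tol, max_iter=max_iter
        )
        arousal_mod.write_estimates(outdir, ar_est, ar_params, impulses.t_grid)
        ar_times = impulses.times

        stage = "eeg-power"
        beta_by_session = {}
        if bundle.eeg is not None:
            clean = eeg_mod.preprocess(bundle.eeg)
            band = tuple(config.get("band", BETA_BAND))
            summaries = eeg_mod.session_band_power(clean, bundle.annotations, band)
            baseline_label = config.get("baseline", bundle.annotations[0][0])
            eeg_mod.relative_band_change(summaries, baseline_label)
            beta_by_session = {s.label: s.mean_power for s in summaries}

        stage = "summaries"
        cells = summarize_sessions(
            bundle, perf_est, ar_est, ar_times, beta_by_session
        )
        summary_df = pd.DataFrame([vars(c) for c in cells])
        summary_df.to_csv(outdir / "summaries.csv", index=False)

        stage = "relationships"
        perf_n = minmax_normalize(perf_est.mean)
        ar_at_trials = np.interp(bundle.trial_onsets, ar_times, ar_est.mean)
        ar_n = minmax_normalize(ar_at_trials)
        quad = fit_inverted_u(ar_n, perf_n)
        relationships = {
            "inverted_u": {
                "c0": quad.c0, "c1": quad.c1, "c2": quad.c2,
                "concave": quad.concave, "vertex": quad.vertex,
            }
        }
        sess_perf = summary_df.groupby("session")["mean_perf"].mean()
        if beta_by_session and len(sess_perf) >= 3:
            labels = [l for l in sess_perf.index if l in beta_by_session]
            slope, icept, r, p = fit_linear_relation(
                [beta_by_session[l] for l in labels],
                minmax_normalize(sess_perf[labels].to_numpy()),
            )
            relationships["beta_linear"] = {
                "slope": slope, "intercept": icept, "r": r, "p": p,
            }
        (outdir / "relationships.json").write_text(
            json.dumps(relationships, indent=2)
        )

        stage = "anova"
        segs = align_streams(bundle)
        groups = [
            perf_est.mean[segs[l]["trials"]]
            for l in segs
            if segs[l]["trials"].size >= 2
        ]
        if len(groups) >= 2:
            F, p = anova_oneway(groups)
        else:
            F, p = np.nan, np.nan
        pd.DataFrame(
            [{"metric": "mean_perf_by_session", "F": F, "p": p,
              "note": "raw p-values; no multiple-testing correction"}]
        ).to_csv(outdir / "anova.csv", index=False)
    except Exception as exc:
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("cogwear").removeHandler(handler)
        handler.close()

    return {
        "bundle": bundle,
        "performance": {"params": perf_params, "estimate": perf_est,
                        "diagnostics": perf_diag},
        "deconvolution": dres,
        "arousal": {"params": ar_params, "estimate": ar_est,
                    "diagnostics": ar_diag},
        "beta_by_session": beta_by_session,
        "summaries": summary_df,
        "relationships": relationships,
        "anova": {"F": F, "p": p},
        "output_dir": outdir,
    }
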