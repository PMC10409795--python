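"""EEG cleaning, constant-Q spectrogram, and beta-band power summaries.

Four-channel headband EEG (TP9, AF7, AF8, TP10, sampled at 256 Hz) is
band-pass filtered to 1–50 Hz with a zero-phase filter, decimated to 128 Hz,
and cleaned by a burst criterion: sliding-window RMS whose z-score exceeds a
threshold flags the window as artifact, and flagged frames are excluded from
downstream averages (the data themselves are never altered).  A constant-Q
filterbank (geometrically spaced bins, Gaussian windows in frequency) yields
a time–frequency magnitude array from which the mean beta-band (13–30 Hz)
power per labeled session interval is summarized, with percent change against
a baseline session.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "BandPowerSummary",
    "preprocess",
    "spectrogram_cq",
    "band_power",
    "relative_band_change",
    "session_band_power",
    "read_eeg_csv",
]

CHANNELS = ("TP9", "AF7", "AF8", "TP10")
TEMPORAL_CHANNELS = ("TP9", "TP10")
BETA_BAND = (13.0, 30.0)


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts with an optional artifact mask."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    channels: tuple = CHANNELS
    start_time: float = 0.0
    artifact_mask: np.ndarray | None = None  # True = contaminated sample

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channels):
            raise ValueError("one row of samples per channel required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.artifact_mask is not None and (
            self.artifact_mask.size != self.samples.shape[1]
        ):
            raise ValueError("artifact mask must align with samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channels.index(name)]


@dataclass
class BandPowerSummary:
    """Mean band power (squared CQ magnitude, arbitrary units) per interval."""

    label: str
    band: tuple
    mean_power: float
    n_frames: int
    pct_change_vs_baseline: float | None = None
    undefined: bool = field(default=False)


def preprocess(
    raw: EEGRecording,
    target_fs: float = 128.0,
    burst_window_s: float = 1.0,
    burst_hop_s: float = 0.5,
    burst_z: float = 5.0,
) -> EEGRecording:
    """Band-pass 1–50 Hz, decimate to 128 Hz, and mask RMS bursts.

    Filtering is zero-phase (no latency shift against the session
    annotations).  The burst mask marks samples whose 1 s window RMS z-score
    exceeds ``burst_z`` on any channel; masked frames are dropped from
    averages downstream rather than interpolated.
    """
    if raw.fs < 128:
        raise ValueError("EEG sampling rate below 128 Hz is not supported")
    if raw.fs != 256:
        warnings.warn(f"expected 256 Hz headband EEG, got {raw.fs} Hz")

    sos = signal.butter(4, [1.0, 50.0], btype="bandpass", fs=raw.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, raw.samples, axis=1)

    q = int(round(raw.fs / target_fs))
    if q > 1:
        filtered = signal.decimate(filtered, q, axis=1, zero_phase=True)
    fs_out = raw.fs / q

    win = int(round(burst_window_s * fs_out))
    hop = int(round(burst_hop_s * fs_out))
    n = filtered.shape[1]
    mask = np.zeros(n, dtype=bool)
    starts = np.arange(0, max(n - win + 1, 1), hop)
    rms = np.array(
        [np.sqrt(np.mean(filtered[:, s : s + win] ** 2, axis=1)) for s in starts]
    )  # (n_windows, n_channels)
    mu = rms.mean(axis=0)
    sd = rms.std(axis=0)
    sd = np.where(sd > 0, sd, np.inf)
    bad = ((rms - mu) / sd > burst_z).any(axis=1)
    for s, b in zip(starts, bad):
        if b:
            mask[s : s + win] = True
    if bad.any():
        log.info("burst rejection masked %d/%d windows", int(bad.sum()), bad.size)

    return EEGRecording(
        samples=filtered,
        fs=fs_out,
        channels=raw.channels,
        start_time=raw.start_time,
        artifact_mask=mask,
    )


def spectrogram_cq(
    x: np.ndarray,
    fs: float,
    f_range: tuple = (1.0, 50.0),
    bins_per_octave: int = 12,
    hop_s: float = 0.25,
):
    """Constant-Q time–frequency magnitude of one channel.

    Geometrically spaced center frequencies over ``f_range``; each bin is an
    FFT-domain Gaussian band-pass whose bandwidth is proportional to its
    center frequency (Q = 1/(2^(1/b) - 1)), i.e. a nonstationary
    Gabor-style analysis.  Returns (freqs, frame_times, magnitude) with
    magnitude shaped (n_bins, n_frames).
    """
    f_lo, f_hi = f_range
    if not 0 < f_lo < f_hi < fs / 2:
        raise ValueError("frequency range must satisfy 0 < f_lo < f_hi < fs/2")
    x = np.asarray(x, dtype=float)
    n = x.size
    n_bins = int(np.ceil(bins_per_octave * np.log2(f_hi / f_lo))) + 1
    freqs = f_lo * 2.0 ** (np.arange(n_bins) / bins_per_octave)
    freqs = freqs[freqs <= f_hi]

    Q = 1.0 / (2.0 ** (1.0 / bins_per_octave) - 1.0)
    X = np.fft.fft(x)
    f_axis = np.fft.fftfreq(n, d=1.0 / fs)
    hop = max(int(round(hop_s * fs)), 1)
    frame_idx = np.arange(0, n, hop)
    mag = np.empty((freqs.size, frame_idx.size))
    pos = f_axis > 0
    for i, fc in enumerate(freqs):
        sigma_f = fc / Q / 2.0
        win = np.zeros(n)
        win[pos] = 2.0 * np.exp(-0.5 * ((f_axis[pos] - fc) / sigma_f) ** 2)
        band = np.fft.ifft(X * win)  # analytic band-limited signal
        mag[i] = np.abs(band[frame_idx])
    frame_times = frame_idx / fs
    return freqs, frame_times, mag


def band_power(
    freqs: np.ndarray,
    frame_times: np.ndarray,
    mag: np.ndarray,
    band: tuple,
    intervals,
    artifact_mask: np.ndarray | None = None,
    mask_fs: float | None = None,
):
    """Mean squared CQ magnitude per labeled interval within ``band``.

    ``intervals`` is an iterable of (label, start_s, end_s) half-open spans.
    Frames overlapping masked samples are excluded; a fully masked or empty
    interval yields an ``undefined`` summary rather than an error.
    """
    f_lo, f_hi = band
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    if not in_band.any() or f_lo >= f_hi:
        raise ValueError(f"band {band} selects no frequency bins")
    frame_ok = np.ones(frame_times.size, dtype=bool)
    if artifact_mask is not None:
        if mask_fs is None:
            raise ValueError("mask_fs required alongside artifact_mask")
        idx = np.minimum(
            (frame_times * mask_fs).astype(int), artifact_mask.size - 1
        )
        frame_ok = ~artifact_mask[idx]

    out = []
    power = mag[in_band] ** 2
    for label, start, end in intervals:
        sel = (frame_times >= start) & (frame_times < end) & frame_ok
        if not sel.any():
            out.append(
                BandPowerSummary(label, (f_lo, f_hi), np.nan, 0, undefined=True)
            )
            continue
        out.append(
            BandPowerSummary(
                label, (f_lo, f_hi), float(power[:, sel].mean()), int(sel.sum())
            )
        )
    return out


def relative_band_change(summaries, baseline_label: str):
    """Percent change of each interval's power against the baseline interval."""
    base = next((s for s in summaries if s.label == baseline_label), None)
    if base is None:
        raise ValueError(f"baseline interval {baseline_label!r} not found")
    for s in summaries:
        if base.undefined or base.mean_power == 0 or s.undefined:
            s.pct_change_vs_baseline = None
        else:
            s.pct_change_vs_baseline = (
                100.0 * (s.mean_power - base.mean_power) / base.mean_power
            )
    return summaries


def session_band_power(
    recording: EEGRecording,
    intervals,
    band: tuple = BETA_BAND,
    channels: tuple = TEMPORAL_CHANNELS,
    bins_per_octave: int = 12,
):
    """Preprocessed-recording band power averaged over the given channels.

    Defaults to the temporoparietal pair (TP9, TP10).  Returns one summary
    per interval with powers averaged across channels.
    """
    per_channel = []
    for name in channels:
        freqs, ft, mag = spectrogram_cq(
            recording.channel(name), recording.fs, bins_per_octave=bins_per_octave
        )
        per_channel.append(
            band_power(
                freqs, ft, mag, band, intervals,
                artifact_mask=recording.artifact_mask, mask_fs=recording.fs,
            )
        )
    out = []
    for summaries in zip(*per_channel):
        ok = [s for s in summaries if not s.undefined]
        if not ok:
            out.append(summaries[0])
            continue
        s0 = summaries[0]
        out.append(
            BandPowerSummary(
                s0.label,
                s0.band,
                float(np.mean([s.mean_power for s in ok])),
                int(np.sum([s.n_frames for s in ok])),
            )
        )
    return out


def read_eeg_csv(path) -> EEGRecording:
    """Read headband EEG CSV with header ``timestamp,TP9,AF7,AF8,TP10``."""
    df = pd.read_csv(path)
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing EEG channels {missing}")
    ts = df["timestamp"].to_numpy(float)
    if ts.size < 2:
        raise ValueError(f"{path}: too few samples")
    fs = 1.0 / float(np.median(np.diff(ts)))
    return EEGRecording(
        samples=df[list(CHANNELS)].to_numpy(float).T,
        fs=round(fs),
        start_time=float(ts[0]),
    )
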