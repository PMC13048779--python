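"""Signal conditioning and windowing for multi-channel physiological recordings.

All filters are applied zero-phase (forward-backward second-order sections),
which preserves the timing of skin-conductance responses and other transient
physiological events. Per-modality pipelines bundle the conditioning steps
conventionally applied to each channel type before feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "TimeSeries",
    "Window",
    "butterworth",
    "notch",
    "median_filter",
    "resample_to",
    "minmax_normalize",
    "rms_envelope",
    "make_windows",
    "preprocess_eda_external",
    "preprocess_ecg",
    "preprocess_ppg",
    "preprocess_emg",
    "preprocess_resp",
    "preprocess_skt",
    "read_subject_csv",
]


class DegenerateInputError(ValueError):
    """Raised when an operation is undefined for the given input (e.g. a
    constant signal passed to min-max normalization)."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    values : ndarray
        Sample values.
    fs : float
        Sampling rate in Hz, > 0.
    units : str
        Physical units of the samples (e.g. ``"uS"`` for microsiemens).
    channel : str
        Channel name (e.g. ``"eda"``, ``"ecg"``).
    """

    values: np.ndarray
    fs: float
    units: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds (first sample at t = 0)."""
        return np.arange(self.n) / self.fs

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class Window:
    """A fixed-length slice of all channels with its affect label.

    The label is the (arousal, valence) pair read from the annotation traces,
    by default at the window's center sample.
    """

    channels: dict[str, np.ndarray]
    fs: Mapping[str, float]
    start_s: float
    win_len_s: float
    label: tuple[float, float] | None
    subject_id: str = ""

    @property
    def center_s(self) -> float:
        return self.start_s + self.win_len_s / 2.0

    @property
    def arousal(self) -> float | None:
        return None if self.label is None else self.label[0]

    @property
    def valence(self) -> float | None:
        return None if self.label is None else self.label[1]

    def series(self, channel: str) -> TimeSeries:
        return TimeSeries(self.channels[channel], fs=self.fs[channel], channel=channel)


def _check_cutoffs(cutoffs: Sequence[float], fs: float) -> np.ndarray:
    c = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    nyq = fs / 2.0
    if np.any(c <= 0) or np.any(c >= nyq):
        raise ValueError(
            f"cutoff frequencies {c.tolist()} must lie strictly inside (0, Nyquist={nyq})"
        )
    return c


def butterworth(
    ts: TimeSeries,
    kind: str,
    cutoffs: float | Sequence[float],
    order: int = 3,
) -> TimeSeries:
    """Zero-phase Butterworth filter.

    ``kind`` is one of ``"lowpass"``, ``"highpass"``, ``"bandpass"``,
    ``"bandstop"``. Applied forward-backward, so the effective magnitude
    response is the square of the single-pass Butterworth response and the
    phase response is identically zero.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if kind not in ("lowpass", "highpass", "bandpass", "bandstop"):
        raise ValueError(f"unknown filter kind {kind!r}")
    c = _check_cutoffs(cutoffs, ts.fs)
    if kind in ("bandpass", "bandstop"):
        if c.size != 2 or c[0] >= c[1]:
            raise ValueError("band filters need two increasing cutoffs")
    wn = c if c.size > 1 else float(c[0])
    sos = signal.butter(order, wn, btype=kind, fs=ts.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.values)
    return ts.with_values(filtered)


def notch(ts: TimeSeries, freq: float, quality: float = 30.0) -> TimeSeries:
    """Zero-phase IIR notch (power-line interference removal)."""
    _check_cutoffs([freq], ts.fs)
    b, a = signal.iirnotch(freq, quality, fs=ts.fs)
    return ts.with_values(signal.filtfilt(b, a, ts.values))


def median_filter(ts: TimeSeries, window_samples: int) -> TimeSeries:
    """Running median with edge replication.

    Even window lengths are incremented to the next odd value so the kernel
    is symmetric about each sample.
    """
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    if window_samples % 2 == 0:
        window_samples += 1
    if window_samples > ts.n:
        raise ValueError(
            f"median window ({window_samples}) larger than signal ({ts.n})"
        )
    out = ndimage.median_filter(ts.values, size=window_samples, mode="nearest")
    return ts.with_values(out)


def resample_to(ts: TimeSeries, target_fs: float) -> TimeSeries:
    """Resample to ``target_fs`` with polyphase filtering (anti-aliased)."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if np.isclose(target_fs, ts.fs):
        return replace(ts, fs=float(target_fs))
    ratio = Fraction(target_fs / ts.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    out = signal.resample_poly(ts.values, up, down, padtype="line")
    n_target = int(round(ts.n * target_fs / ts.fs))
    if out.size > n_target:
        out = out[:n_target]
    elif out.size < n_target:
        out = np.pad(out, (0, n_target - out.size), mode="edge")
    return replace(ts, values=out, fs=float(target_fs))


def minmax_normalize(ts: TimeSeries) -> TimeSeries:
    """Affinely map the signal onto [0, 1]. Errors on constant input."""
    lo, hi = float(np.min(ts.values)), float(np.max(ts.values))
    if hi - lo <= 0:
        raise DegenerateInputError("cannot min-max normalize a constant signal")
    return ts.with_values((ts.values - lo) / (hi - lo))


def rms_envelope(ts: TimeSeries, window_s: float = 0.1) -> TimeSeries:
    """Root-mean-square envelope over a sliding window (rectify + smooth)."""
    w = max(1, int(round(window_s * ts.fs)))
    sq = ts.values**2
    kernel = np.ones(w) / w
    env = np.sqrt(np.convolve(sq, kernel, mode="same"))
    return ts.with_values(env)


# ---------------------------------------------------------------------------
# Per-modality pipelines
# ---------------------------------------------------------------------------

def preprocess_eda_external(ts: TimeSeries, target_fs: float = 20.0) -> TimeSeries:
    """Conditioning for EDA from heterogeneous acquisition hardware:
    downsample to a common rate (default 20 Hz), 1 Hz 3rd-order low-pass,
    21-sample running median, then min-max scaling to absorb inter-subject
    amplitude differences."""
    out = ts
    if not np.isclose(out.fs, target_fs):
        out = resample_to(out, target_fs)
    out = butterworth(out, "lowpass", 1.0, order=3)
    out = median_filter(out, 20)  # promoted to 21 for a symmetric kernel
    return minmax_normalize(out)


def preprocess_ecg(ts: TimeSeries) -> TimeSeries:
    """0.5-40 Hz 3rd-order band-pass (baseline wander + HF noise removal)."""
    return butterworth(ts, "bandpass", (0.5, 40.0), order=3)


def preprocess_ppg(ts: TimeSeries) -> TimeSeries:
    """0.7-3.5 Hz 3rd-order band-pass isolating the cardiac band (42-210 bpm)."""
    return butterworth(ts, "bandpass", (0.7, 3.5), order=3)


def preprocess_emg(ts: TimeSeries, notch_hz: float = 50.0) -> tuple[TimeSeries, TimeSeries]:
    """EMG conditioning: 20-450 Hz band-pass, power-line notch, then a 100 ms
    RMS envelope. Returns ``(bandpassed, envelope)`` — frequency features are
    computed on the band-passed signal, amplitude features on the envelope."""
    band = butterworth(ts, "bandpass", (20.0, min(450.0, ts.fs / 2 * 0.98)), order=3)
    band = notch(band, notch_hz)
    return band, rms_envelope(band, 0.1)


def preprocess_resp(ts: TimeSeries) -> TimeSeries:
    """Respiration: 0.1-0.5 Hz 2nd-order band-pass + 0.05 Hz high-pass, then
    amplitude normalization."""
    out = butterworth(ts, "bandpass", (0.1, 0.5), order=2)
    out = butterworth(out, "highpass", 0.05, order=2)
    peak = float(np.max(np.abs(out.values)))
    if peak > 0:
        out = out.with_values(out.values / peak)
    return out


def preprocess_skt(ts: TimeSeries) -> TimeSeries:
    """Skin temperature: 0.1 Hz low-pass + linear detrend of measurement drift."""
    out = butterworth(ts, "lowpass", 0.1, order=2)
    return out.with_values(signal.detrend(out.values, type="linear"))


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def make_windows(
    channels: Mapping[str, TimeSeries],
    annotations: Mapping[str, TimeSeries] | None = None,
    win_len_s: float = 60.0,
    overlap: float = 0.5,
    subject_id: str = "",
    label_mode: str = "center",
) -> list[Window]:
    """Slice all channels into fixed-length windows with fractional overlap.

    Windows start at 0, hop, 2*hop, ... with ``hop = win_len_s * (1 - overlap)``
    and are kept only while fully inside the record. The label is the
    annotation value at the window center (``label_mode="center"``) or the
    per-window mean (``label_mode="mean"``).
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if win_len_s <= 0:
        raise ValueError("win_len_s must be positive")
    if label_mode not in ("center", "mean"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    duration = min(ts.duration_s for ts in channels.values())
    hop = win_len_s * (1.0 - overlap)
    windows: list[Window] = []
    start = 0.0
    eps = 1e-9
    while start + win_len_s <= duration + eps:
        slices: dict[str, np.ndarray] = {}
        rates: dict[str, float] = {}
        for name, ts in channels.items():
            i0 = int(round(start * ts.fs))
            i1 = i0 + int(round(win_len_s * ts.fs))
            slices[name] = ts.values[i0:i1]
            rates[name] = ts.fs
        label = None
        if annotations is not None:
            label = tuple(
                _label_value(annotations[key], start, win_len_s, label_mode)
                for key in ("arousal", "valence")
            )
        windows.append(
            Window(
                channels=slices,
                fs=rates,
                start_s=start,
                win_len_s=win_len_s,
                label=label,
                subject_id=subject_id,
            )
        )
        start += hop
    return windows


def _label_value(ts: TimeSeries, start: float, win_len: float, mode: str) -> float:
    if mode == "center":
        idx = min(int(round((start + win_len / 2.0) * ts.fs)), ts.n - 1)
        return float(ts.values[idx])
    i0 = int(round(start * ts.fs))
    i1 = min(i0 + int(round(win_len * ts.fs)), ts.n)
    return float(np.mean(ts.values[i0:i1]))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_subject_csv(
    path,
    channel_columns: Sequence[str] | None = None,
    time_column: str = "time_s",
    units: Mapping[str, str] | None = None,
) -> tuple[dict[str, TimeSeries], dict[str, TimeSeries]]:
    """Read a per-subject CSV (time column + channel columns + arousal/valence).

    The sampling rate is inferred from the time column, which must be
    uniformly spaced. Returns ``(channels, annotations)`` where annotations
    holds the ``arousal`` and ``valence`` traces if present.
    """
    df = pd.read_csv(path)
    if time_column not in df.columns:
        raise ValueError(f"missing time column {time_column!r}")
    t = df[time_column].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples to infer sampling rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("time column is not uniformly sampled")
    fs = 1.0 / float(dt[0])
    units = dict(units or {})
    if channel_columns is None:
        channel_columns = [
            c for c in df.columns if c not in (time_column, "arousal", "valence")
        ]
    channels = {
        c: TimeSeries(df[c].to_numpy(dtype=float), fs=fs, units=units.get(c, ""), channel=c)
        for c in channel_columns
    }
    annotations = {
        c: TimeSeries(df[c].to_numpy(dtype=float), fs=fs, channel=c)
        for c in ("arousal", "valence")
        if c in df.columns
    }
    return channels, annotations
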