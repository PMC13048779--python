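"""Seeded generators for synthetic physiological recordings with known truth.

The generators emulate the structure of a continuously annotated emotion
dataset: a skin-conductance channel with a slowly varying tonic level plus
phasic skin-conductance responses (SCRs), optional companion channels (ECG,
PPG, respiration, skin temperature, EMG), and continuous arousal/valence
annotation traces on the 0.5-9.5 rating scale. Every generator is a pure
function of its arguments including the seed, so tests and experiments are
bit-reproducible.

The affect coupling is explicit and recorded in the returned truth block:
arousal drives the SCR rate and amplitude (sympathetic activation), valence
drives the tonic drift. Parameter-recovery tests exploit this known coupling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .preprocess import TimeSeries

__all__ = [
    "ScrEvent",
    "SyntheticSubject",
    "QUADRANTS",
    "scr_kernel",
    "gen_eda",
    "gen_annotations",
    "gen_ecg",
    "gen_ppg",
    "gen_resp",
    "gen_skt",
    "gen_emg",
    "gen_subject",
    "write_subject_csv",
]

#: Quadrant name -> (arousal target, valence target) on the 0.5-9.5 scale.
QUADRANTS: dict[str, tuple[float, float]] = {
    "LALV": (2.5, 2.5),
    "LAHV": (2.5, 7.5),
    "HALV": (7.5, 2.5),
    "HAHV": (7.5, 7.5),
    "Neutral": (5.0, 5.0),
}


@dataclass(frozen=True)
class ScrEvent:
    """A single skin-conductance response: bi-exponential rise-and-decay
    transient added to the tonic baseline.

    ``amplitude`` is the peak height in microsiemens; ``rise_tau`` and
    ``decay_tau`` are the rise and recovery time constants in seconds
    (decay slower than rise for the characteristic SCR asymmetry).
    """

    onset_time: float
    amplitude: float
    rise_tau: float = 0.75
    decay_tau: float = 4.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("SCR amplitude must be positive")
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("need decay_tau > rise_tau > 0")


@dataclass
class SyntheticSubject:
    """One simulated participant: channels, annotation traces, and the
    generator parameters (ground truth) that produced them."""

    subject_id: str
    channels: dict[str, TimeSeries]
    annotations: dict[str, TimeSeries]
    truth: dict


def scr_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak SCR shape ``(1 - exp(-t/rise)) * exp(-t/decay)`` for t >= 0.

    Normalized so the kernel maximum is exactly 1; the peak occurs at
    ``t* = rise_tau * log(1 + decay_tau/rise_tau)``.
    """
    t = np.asarray(t, dtype=float)
    h = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / rise_tau)) * np.exp(-np.maximum(t, 0) / decay_tau), 0.0)
    t_peak = rise_tau * np.log1p(decay_tau / rise_tau)
    peak = (1.0 - np.exp(-t_peak / rise_tau)) * np.exp(-t_peak / decay_tau)
    return h / peak


def gen_eda(
    duration_s: float,
    fs: float = 8.0,
    tonic_params: Mapping[str, float] | None = None,
    scr_events: Sequence[ScrEvent] = (),
    noise_sd: float = 0.01,
    seed: int = 0,
) -> TimeSeries:
    """Synthesize an EDA trace: tonic baseline + SCR kernels + Gaussian noise.

    ``tonic_params`` accepts ``level`` (μS, default 2.0), ``slope`` (μS/s,
    default 0) and ``drift_amp``/``drift_period_s`` for a slow sinusoidal
    wander (defaults 0 / 300 s).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    p = {"level": 2.0, "slope": 0.0, "drift_amp": 0.0, "drift_period_s": 300.0}
    p.update(tonic_params or {})
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = p["level"] + p["slope"] * t
    if p["drift_amp"]:
        x = x + p["drift_amp"] * np.sin(2 * np.pi * t / p["drift_period_s"])
    for ev in scr_events:
        x = x + ev.amplitude * scr_kernel(t - ev.onset_time, ev.rise_tau, ev.decay_tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=n)
    return TimeSeries(x, fs=fs, units="uS", channel="eda")


def gen_annotations(
    duration_s: float,
    fs: float = 8.0,
    quadrant_schedule: Sequence[str] = ("Neutral",),
    seed: int = 0,
    jitter_sd: float = 0.25,
    ar_coeff: float = 0.95,
) -> dict[str, TimeSeries]:
    """Piecewise-constant quadrant targets plus small AR(1) jitter, clipped
    to the 0.5-9.5 rating scale. Each schedule entry occupies an equal share
    of the duration."""
    for q in quadrant_schedule:
        if q not in QUADRANTS:
            raise ValueError(f"unknown quadrant {q!r}; expected one of {sorted(QUADRANTS)}")
    n = int(round(duration_s * fs))
    n_blocks = len(quadrant_schedule)
    block_len = n // n_blocks
    rng = np.random.default_rng(seed)
    traces = {}
    for dim_idx, dim in enumerate(("arousal", "valence")):
        target = np.empty(n)
        for b, q in enumerate(quadrant_schedule):
            i0 = b * block_len
            i1 = n if b == n_blocks - 1 else (b + 1) * block_len
            target[i0:i1] = QUADRANTS[q][dim_idx]
        jitter = np.zeros(n)
        innov_sd = jitter_sd * np.sqrt(1 - ar_coeff**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        for i in range(1, n):
            jitter[i] = ar_coeff * jitter[i - 1] + eps[i]
        traces[dim] = TimeSeries(
            np.clip(target + jitter, 0.5, 9.5), fs=fs, channel=dim
        )
    return traces


# ---------------------------------------------------------------------------
# Companion modalities
# ---------------------------------------------------------------------------

def gen_ecg(
    duration_s: float, fs: float = 250.0, bpm: float = 60.0, seed: int = 0,
    noise_sd: float = 0.0, dropout_beats: Sequence[int] = (),
) -> TimeSeries:
    """Idealized ECG as a narrow-spike R-wave train at a constant heart
    rate; optional beats removed to exercise artifact correction."""
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    period = 60.0 / bpm
    beat_times = np.arange(0.5, duration_s, period)
    keep = [i for i in range(beat_times.size) if i not in set(dropout_beats)]
    for bt in beat_times[keep]:
        idx = int(round(bt * fs))
        if 1 <= idx < n - 1:
            x[idx] = 1.0
            x[idx - 1] = x[idx + 1] = 0.35
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n)
    return TimeSeries(x, fs=fs, units="mV", channel="ecg")


def gen_ppg(
    duration_s: float, fs: float = 100.0, bpm: float = 60.0, delay_s: float = 0.2,
    seed: int = 0, noise_sd: float = 0.0,
) -> TimeSeries:
    """Pulse wave train: smooth raised-cosine pulses delayed ``delay_s``
    after the corresponding R peaks (the pulse transit time)."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    period = 60.0 / bpm
    width = min(0.35, period / 2.5)
    for bt in np.arange(0.5 + delay_s, duration_s, period):
        mask = np.abs(t - bt) < width / 2
        x[mask] += 0.5 * (1 + np.cos(2 * np.pi * (t[mask] - bt) / width))
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n)
    return TimeSeries(x, fs=fs, units="au", channel="ppg")


def gen_resp(duration_s: float, fs: float = 8.0, rate_bpm: float = 15.0,
             amplitude: float = 1.0, seed: int = 0, noise_sd: float = 0.0) -> TimeSeries:
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = amplitude * np.sin(2 * np.pi * (rate_bpm / 60.0) * t)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n)
    return TimeSeries(x, fs=fs, units="au", channel="resp")


def gen_skt(duration_s: float, fs: float = 8.0, base_c: float = 32.5,
            slope_c_per_s: float = 0.0, seed: int = 0, noise_sd: float = 0.0) -> TimeSeries:
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = base_c + slope_c_per_s * t
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n)
    return TimeSeries(x, fs=fs, units="degC", channel="skt")


def gen_emg(duration_s: float, fs: float = 1000.0, burst_rate_hz: float = 0.2,
            tone_hz: float = 100.0, amplitude: float = 0.5, seed: int = 0,
            noise_sd: float = 0.02) -> TimeSeries:
    """Surface-EMG stand-in: band-limited carrier amplitude-modulated by
    random activation bursts."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    envelope = 0.2 * np.ones(n)
    n_bursts = rng.poisson(burst_rate_hz * duration_s)
    for _ in range(n_bursts):
        c = rng.uniform(0, duration_s)
        envelope += np.exp(-0.5 * ((t - c) / 0.4) ** 2)
    x = amplitude * envelope * np.sin(2 * np.pi * tone_hz * t)
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, n)
    return TimeSeries(x, fs=fs, units="mV", channel="emg")


# ---------------------------------------------------------------------------
# Whole-subject generation
# ---------------------------------------------------------------------------

#: Default affect coupling: arousal -> SCR rate/amplitude, valence -> tonic slope.
DEFAULT_COUPLING: dict[str, float] = {
    "scr_rate_per_arousal": 0.02,   # SCRs per second per arousal unit
    "scr_amp_per_arousal": 0.06,    # μS of SCR amplitude per arousal unit
    "scr_amp_base": 0.15,           # μS baseline SCR amplitude
    "tonic_per_valence": 0.08,      # μS of tonic offset per valence unit
    "tonic_level": 2.0,             # μS baseline tonic level
    "noise_sd": 0.01,               # μS additive Gaussian noise
}


def gen_subject(
    subject_id: str,
    coupling: Mapping[str, float] | None = None,
    seed: int = 0,
    duration_s: float = 330.0,
    fs: float = 8.0,
    quadrant_schedule: Sequence[str] = ("LALV", "HAHV", "LAHV", "HALV"),
    extra_channels: Sequence[str] = (),
) -> SyntheticSubject:
    """Generate one subject whose EDA is coupled to the annotation traces.

    The SCR event rate follows an inhomogeneous Poisson process with
    intensity ``scr_rate_per_arousal * arousal(t)`` and event amplitudes
    ``scr_amp_base + scr_amp_per_arousal * arousal(onset)``; the tonic level
    tracks ``tonic_level + tonic_per_valence * (valence(t) - 5)``. Setting
    the coupling coefficients to zero yields labels independent of the
    signal, the null condition for leakage and recovery tests.
    """
    coup = dict(DEFAULT_COUPLING)
    coup.update(coupling or {})
    rng = np.random.default_rng(seed)
    ann = gen_annotations(duration_s, fs, quadrant_schedule, seed=int(rng.integers(2**31)))
    arousal = ann["arousal"].values
    valence = ann["valence"].values
    n = arousal.size
    t = np.arange(n) / fs

    # inhomogeneous Poisson SCR onsets by thinning
    rate = coup["scr_rate_per_arousal"] * arousal  # events per second
    events: list[ScrEvent] = []
    if np.any(rate > 0):
        lam_max = float(np.max(rate))
        t_cur = 0.0
        while True:
            t_cur += rng.exponential(1.0 / lam_max)
            if t_cur >= duration_s - 5.0:
                break
            idx = min(int(t_cur * fs), n - 1)
            if rng.uniform() < rate[idx] / lam_max:
                amp = coup["scr_amp_base"] + coup["scr_amp_per_arousal"] * arousal[idx]
                amp *= rng.uniform(0.8, 1.2)
                events.append(ScrEvent(onset_time=t_cur, amplitude=float(max(amp, 1e-3))))

    tonic = coup["tonic_level"] + coup["tonic_per_valence"] * (valence - 5.0)
    x = tonic.copy()
    for ev in events:
        x = x + ev.amplitude * scr_kernel(t - ev.onset_time, ev.rise_tau, ev.decay_tau)
    if coup["noise_sd"] > 0:
        x = x + rng.normal(0.0, coup["noise_sd"], size=n)
    channels = {"eda": TimeSeries(x, fs=fs, units="uS", channel="eda")}

    for name in extra_channels:
        sub_seed = int(rng.integers(2**31))
        mean_arousal = float(np.mean(arousal))
        if name == "ecg":
            channels[name] = gen_ecg(duration_s, bpm=55 + 4 * mean_arousal, seed=sub_seed)
        elif name == "ppg":
            channels[name] = gen_ppg(duration_s, bpm=55 + 4 * mean_arousal, seed=sub_seed)
        elif name == "resp":
            channels[name] = gen_resp(duration_s, fs=fs, rate_bpm=10 + mean_arousal,
                                      seed=sub_seed, noise_sd=0.02)
        elif name == "skt":
            channels[name] = gen_skt(duration_s, fs=fs, seed=sub_seed, noise_sd=0.01)
        elif name == "emg":
            channels[name] = gen_emg(duration_s, seed=sub_seed)
        else:
            raise ValueError(f"unknown channel {name!r}")

    truth = {
        "subject_id": subject_id,
        "seed": seed,
        "coupling": coup,
        "quadrant_schedule": list(quadrant_schedule),
        "n_scr_events": len(events),
        "scr_onsets": [ev.onset_time for ev in events],
        "duration_s": duration_s,
        "fs": fs,
    }
    return SyntheticSubject(subject_id, channels, ann, truth)


def write_subject_csv(subject: SyntheticSubject, directory: str | Path) -> Path:
    """Write one subject as CSV (time_s + channels resampled to the EDA rate
    + arousal/valence) with a JSON truth sidecar. Returns the CSV path."""
    import pandas as pd

    from .preprocess import resample_to

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fs = subject.channels["eda"].fs
    n = subject.channels["eda"].n
    data = {"time_s": np.arange(n) / fs}
    for name, ts in subject.channels.items():
        r = ts if np.isclose(ts.fs, fs) else resample_to(ts, fs)
        data[name] = r.values[:n]
    for name, ts in subject.annotations.items():
        data[name] = ts.values[:n]
    csv_path = directory / f"{subject.subject_id}.csv"
    pd.DataFrame(data).to_csv(csv_path, index=False)
    (directory / f"{subject.subject_id}.truth.json").write_text(
        json.dumps(subject.truth, indent=1)
    )
    return csv_path
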