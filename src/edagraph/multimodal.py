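"""Baseline features from companion physiological channels.

Covers ECG R-peak detection (Pan-Tompkins-style energy pipeline with
plausibility-based RR correction), PPG beat detection from the
second-derivative-enhanced waveform with physiological interval rejection,
heart-rate variability (time and band-power domain), pulse transit time,
respiration, skin temperature, and surface-EMG descriptors for the three
recorded muscles (Zygomaticus, Corrugator, Trapezius).

Missing or degenerate inputs yield NaN markers rather than exceptions so a
feature table stays rectangular.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from .preprocess import TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "BeatSeries",
    "MULTIMODAL_FEATURE_NAMES",
    "detect_r_peaks",
    "detect_ppg_beats",
    "hrv_features",
    "ptt_features",
    "resp_features",
    "skt_features",
    "emg_features",
    "multimodal_feature_vector",
]

#: Physiologically plausible inter-beat interval range in seconds (40-216 bpm).
IBI_BOUNDS_S = (0.277, 1.5)

HRV_BANDS = {"VLF": (0.0033, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}

_HRV_NAMES = ("IHR_mean", "IHR_std", "IHR_min", "IHR_max", "SDNN", "RMSSD",
              "pNN50", "HRV_VLF", "HRV_LF", "HRV_HF", "HRV_LFHF")
_PTT_NAMES = ("PTT_mean", "PTT_std", "PTT_min", "PTT_max", "PTT_slope")
_RESP_NAMES = ("RESP_mean", "RESP_std", "RESP_min", "RESP_max", "RESP_rate",
               "RESP_pp_amp", "RESP_IE_ratio", "RESP_var")
_TEMP_NAMES = ("TEMP_mean", "TEMP_std", "TEMP_min", "TEMP_max", "TEMP_slope")
_EMG_BASE = ("rms", "mav", "ssi", "wl", "medfreq", "meanfreq", "kurt", "skew")
_EMG_PREFIXES = ("ZEMG", "CEMG", "TEMG")

#: Frozen 53-feature multimodal roster: 11 HRV + 5 PTT + 8 RESP + 5 TEMP +
#: 8 EMG descriptors for each of three muscles.
MULTIMODAL_FEATURE_NAMES: tuple[str, ...] = (
    _HRV_NAMES + _PTT_NAMES + _RESP_NAMES + _TEMP_NAMES
    + tuple(f"{p}_{b}" for p in _EMG_PREFIXES for b in _EMG_BASE)
)
assert len(MULTIMODAL_FEATURE_NAMES) == 53


@dataclass(frozen=True)
class BeatSeries:
    """Cardiac event times in seconds, strictly increasing."""

    event_times: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.event_times.size

    def intervals(self) -> np.ndarray:
        """Inter-beat intervals in seconds."""
        return np.diff(self.event_times)


# ---------------------------------------------------------------------------
# Beat detection
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: TimeSeries) -> BeatSeries:
    """R-peak detection via the classic energy pipeline: differentiate,
    square, moving-window integrate, adaptive threshold, then refine each
    detection to the local ECG maximum. RR intervals outside physiological
    bounds are corrected by cubic-spline interpolation of the beat times.
    """
    x = ecg.values
    if np.ptp(x) < 1e-12:
        logger.warning("flat ECG signal: no beats detected")
        return BeatSeries(np.empty(0), source="ecg")
    deriv = np.gradient(x) * ecg.fs
    sq = deriv**2
    w = max(1, int(round(0.15 * ecg.fs)))
    integ = np.convolve(sq, np.ones(w) / w, mode="same")
    thresh = 0.25 * np.max(integ)
    min_dist = max(1, int(round(IBI_BOUNDS_S[0] * ecg.fs)))
    cand, _ = signal.find_peaks(integ, height=thresh, distance=min_dist)
    refine = max(1, int(round(0.1 * ecg.fs)))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - refine), min(x.size, c + refine + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    times = peaks / ecg.fs
    return _correct_rr(times, "ecg")


def _correct_rr(times: np.ndarray, source: str) -> BeatSeries:
    """Replace implausibly long RR gaps (missed beats) by spline-interpolated
    beat times; drop implausibly short intervals (spurious detections)."""
    if times.size < 3:
        return BeatSeries(times, source=source)
    # drop spurious short intervals first
    keep = [0]
    for i in range(1, times.size):
        if times[i] - times[keep[-1]] >= IBI_BOUNDS_S[0]:
            keep.append(i)
    times = times[keep]
    rr = np.diff(times)
    median_rr = float(np.median(rr))
    long_gaps = np.where(rr > min(IBI_BOUNDS_S[1], 1.7 * median_rr))[0]
    if long_gaps.size and times.size >= 4:
        good = np.setdiff1d(np.arange(rr.size), long_gaps)
        if good.size >= 3:
            cs = interpolate.CubicSpline(times[good], rr[good])
            inserted = []
            for gi in long_gaps:
                gap = rr[gi]
                est = float(cs(times[gi]))
                n_missing = max(1, int(round(gap / max(est, IBI_BOUNDS_S[0]))) - 1)
                for m in range(1, n_missing + 1):
                    inserted.append(times[gi] + gap * m / (n_missing + 1))
            times = np.sort(np.concatenate([times, inserted]))
    return BeatSeries(times, source=source)


def detect_ppg_beats(ppg: TimeSeries) -> BeatSeries:
    """PPG beat detection: the second derivative enhances pulse-wave
    inflection points; peaks are picked with a time-adaptive threshold (local
    moving quantile of the detection function) and refined to the systolic
    peak. Inter-beat intervals outside 277-1500 ms are rejected."""
    x = ppg.values
    if np.ptp(x) < 1e-12:
        logger.warning("flat PPG signal: no beats detected")
        return BeatSeries(np.empty(0), source="ppg")
    d2 = np.gradient(np.gradient(x))
    det = np.clip(-d2, 0, None) ** 2  # systolic upstroke curvature
    w = max(1, int(round(2.0 * ppg.fs)))
    kernel = np.ones(w) / w
    local_level = np.convolve(det, kernel, mode="same")
    thresh = 2.0 * local_level + 1e-3 * np.max(det)
    min_dist = max(1, int(round(IBI_BOUNDS_S[0] * ppg.fs)))
    cand, _ = signal.find_peaks(det, distance=min_dist)
    cand = cand[det[cand] > thresh[cand]]
    refine = max(1, int(round(0.25 * ppg.fs)))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - refine), min(x.size, c + refine + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    times = peaks / ppg.fs
    # physiological interval validation
    valid = [0] if times.size else []
    for i in range(1, times.size):
        ibi = times[i] - times[valid[-1]]
        if IBI_BOUNDS_S[0] <= ibi:
            valid.append(i)
        # intervals shorter than the lower bound are rejected as spurious
    return BeatSeries(times[valid] if valid else np.empty(0), source="ppg")


# ---------------------------------------------------------------------------
# Feature groups
# ---------------------------------------------------------------------------

def _nan_block(names) -> dict[str, float]:
    return {n: math.nan for n in names}


def hrv_features(beats: BeatSeries) -> dict[str, float]:
    """Instantaneous-heart-rate statistics, SDNN/RMSSD/pNN50, and VLF/LF/HF
    band powers of the 4 Hz-resampled RR tachogram (Welch estimate)."""
    if beats.n < 3:
        logger.warning("hrv_features: fewer than 3 beats")
        return _nan_block(_HRV_NAMES)
    rr = beats.intervals()  # seconds
    ihr = 60.0 / rr
    out = {
        "IHR_mean": float(np.mean(ihr)),
        "IHR_std": float(np.std(ihr)),
        "IHR_min": float(np.min(ihr)),
        "IHR_max": float(np.max(ihr)),
        "SDNN": float(np.std(rr) * 1000.0),
        "RMSSD": float(np.sqrt(np.mean(np.diff(rr) ** 2)) * 1000.0) if rr.size > 1 else 0.0,
        "pNN50": float(100.0 * np.mean(np.abs(np.diff(rr)) > 0.05)) if rr.size > 1 else 0.0,
    }
    span = beats.event_times[-1] - beats.event_times[0]
    if span >= 60.0 and rr.size >= 4:
        fs_t = 4.0
        t_beats = beats.event_times[1:]
        t_grid = np.arange(t_beats[0], t_beats[-1], 1.0 / fs_t)
        tach = np.interp(t_grid, t_beats, rr)
        tach = signal.detrend(tach)
        nper = min(tach.size, 256)
        freqs, psd = signal.welch(tach, fs=fs_t, nperseg=nper)
        for name, band in HRV_BANDS.items():
            mask = (freqs >= band[0]) & (freqs < band[1])
            out[f"HRV_{name}"] = (
                float(np.trapezoid(psd[mask], freqs[mask])) if mask.sum() > 1 else 0.0
            )
        hf = out["HRV_HF"]
        out["HRV_LFHF"] = out["HRV_LF"] / hf if hf > 0 else math.inf
    else:
        out.update({k: math.nan for k in ("HRV_VLF", "HRV_LF", "HRV_HF", "HRV_LFHF")})
    return out


def ptt_features(ecg_beats: BeatSeries, ppg_beats: BeatSeries,
                 max_ptt_s: float = 0.6) -> dict[str, float]:
    """Per-beat pulse transit time: delay from each R peak to the next PPG
    beat (within ``max_ptt_s``); unmatched beats are skipped."""
    if ecg_beats.n == 0 or ppg_beats.n == 0:
        logger.warning("ptt_features: missing beats in one channel")
        return _nan_block(_PTT_NAMES)
    ptts, times = [], []
    ppg_t = ppg_beats.event_times
    for rt in ecg_beats.event_times:
        nxt = ppg_t[ppg_t > rt]
        if nxt.size and (nxt[0] - rt) <= max_ptt_s:
            ptts.append((nxt[0] - rt) * 1000.0)  # ms
            times.append(rt)
    if len(ptts) < 2:
        logger.warning("ptt_features: fewer than 2 matched beats")
        return _nan_block(_PTT_NAMES)
    ptts = np.asarray(ptts)
    times = np.asarray(times)
    return {
        "PTT_mean": float(np.mean(ptts)),
        "PTT_std": float(np.std(ptts)),
        "PTT_min": float(np.min(ptts)),
        "PTT_max": float(np.max(ptts)),
        "PTT_slope": float(np.polyfit(times, ptts, 1)[0]),  # ms per second
    }


def resp_features(resp: TimeSeries) -> dict[str, float]:
    """Breathing rate from peak intervals, variability, peak-to-peak
    amplitude, and inspiration/expiration ratio from zero crossings."""
    x = resp.values
    if np.ptp(x) < 1e-12:
        return _nan_block(_RESP_NAMES)
    out = {
        "RESP_mean": float(np.mean(x)),
        "RESP_std": float(np.std(x)),
        "RESP_min": float(np.min(x)),
        "RESP_max": float(np.max(x)),
        "RESP_pp_amp": float(np.ptp(x)),
    }
    min_dist = max(1, int(round(1.0 * resp.fs)))  # breaths < 60/min apart
    peaks, _ = signal.find_peaks(x, distance=min_dist, prominence=0.1 * np.ptp(x))
    if peaks.size >= 2:
        intervals = np.diff(peaks) / resp.fs
        out["RESP_rate"] = float(60.0 / np.mean(intervals))
        out["RESP_var"] = float(np.std(intervals))
    else:
        out["RESP_rate"] = math.nan
        out["RESP_var"] = math.nan
    centered = x - np.mean(x)
    pos = centered > 0
    crossings = np.flatnonzero(np.diff(pos.astype(int)))
    if crossings.size >= 2:
        insp = float(np.sum(pos))
        exp = float(np.sum(~pos))
        out["RESP_IE_ratio"] = insp / exp if exp > 0 else math.inf
    else:
        out["RESP_IE_ratio"] = math.nan
    return {k: out[k] for k in _RESP_NAMES}


def skt_features(skt: TimeSeries) -> dict[str, float]:
    x = skt.values
    t = np.arange(x.size) / skt.fs
    return {
        "TEMP_mean": float(np.mean(x)),
        "TEMP_std": float(np.std(x)),
        "TEMP_min": float(np.min(x)),
        "TEMP_max": float(np.max(x)),
        "TEMP_slope": float(np.polyfit(t, x, 1)[0]) if x.size > 1 else 0.0,
    }


def emg_features(emg_band: TimeSeries, envelope: TimeSeries | None = None,
                 muscle: str = "ZEMG") -> dict[str, float]:
    """Eight surface-EMG descriptors for one muscle, prefixed by its tag.

    Amplitude descriptors (RMS, MAV, SSI, waveform length) come from the RMS
    envelope when one is supplied, otherwise from the band-passed signal;
    spectral and distributional descriptors always use the band-passed
    (pre-envelope) signal.
    """
    if muscle not in _EMG_PREFIXES:
        raise ValueError(f"muscle must be one of {_EMG_PREFIXES}")
    x = emg_band.values
    amp = envelope.values if envelope is not None else x
    if np.ptp(x) < 1e-12:
        return _nan_block(f"{muscle}_{b}" for b in _EMG_BASE)
    out = {
        f"{muscle}_rms": float(np.sqrt(np.mean(amp**2))),
        f"{muscle}_mav": float(np.mean(np.abs(amp))),
        f"{muscle}_ssi": float(np.sum(amp**2)),
        f"{muscle}_wl": float(np.sum(np.abs(np.diff(amp)))),
    }
    freqs, psd = signal.periodogram(x - np.mean(x), fs=emg_band.fs)
    total = np.sum(psd)
    if total > 0:
        cum = np.cumsum(psd) / total
        out[f"{muscle}_medfreq"] = float(np.interp(0.5, cum, freqs))
        out[f"{muscle}_meanfreq"] = float(np.sum(freqs * psd) / total)
    else:
        out[f"{muscle}_medfreq"] = out[f"{muscle}_meanfreq"] = math.nan
    from scipy import stats as sps

    out[f"{muscle}_kurt"] = float(sps.kurtosis(x))
    out[f"{muscle}_skew"] = float(sps.skew(x))
    return {f"{muscle}_{b}": out[f"{muscle}_{b}"] for b in _EMG_BASE}


def multimodal_feature_vector(
    ecg: TimeSeries | None = None,
    ppg: TimeSeries | None = None,
    resp: TimeSeries | None = None,
    skt: TimeSeries | None = None,
    emg: dict[str, tuple[TimeSeries, TimeSeries | None]] | None = None,
) -> dict[str, float]:
    """Assemble the 53-feature multimodal vector from whichever channels are
    present; absent channels contribute NaN markers.

    ``emg`` maps muscle tags (ZEMG/CEMG/TEMG) to ``(band, envelope)`` pairs.
    """
    out: dict[str, float] = {}
    ecg_beats = detect_r_peaks(ecg) if ecg is not None else None
    ppg_beats = detect_ppg_beats(ppg) if ppg is not None else None
    out.update(hrv_features(ecg_beats) if ecg_beats is not None else _nan_block(_HRV_NAMES))
    if ecg_beats is not None and ppg_beats is not None:
        out.update(ptt_features(ecg_beats, ppg_beats))
    else:
        out.update(_nan_block(_PTT_NAMES))
    out.update(resp_features(resp) if resp is not None else _nan_block(_RESP_NAMES))
    out.update(skt_features(skt) if skt is not None else _nan_block(_TEMP_NAMES))
    emg = emg or {}
    for tag in _EMG_PREFIXES:
        if tag in emg:
            band, env = emg[tag]
            out.update(emg_features(band, env, muscle=tag))
        else:
            out.update(_nan_block(f"{tag}_{b}" for b in _EMG_BASE))
    assert tuple(out) == MULTIMODAL_FEATURE_NAMES
    return out
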