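"""Traditional electrodermal-activity analysis.

Tonic/phasic decomposition plus the conventional 19-feature roster: phasic
statistics and non-specific SCR count, tonic statistics and slope, the
time-varying sympathetic-tone index (TVSymp) and its summaries, and spectral
band powers.

The decomposition is additive by construction: the tonic component is a
zero-phase low-pass trend (0.05 Hz, order 4) and the phasic component is the
exact residual, so ``tonic + phasic == eda`` to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import DegenerateInputError, TimeSeries, butterworth

__all__ = [
    "EdaDecomposition",
    "TRADITIONAL_FEATURE_NAMES",
    "decompose",
    "detect_nscr",
    "tvsymp_index",
    "eda_frequency_features",
    "traditional_feature_vector",
]

#: Frozen 19-feature roster of the traditional EDA battery.
TRADITIONAL_FEATURE_NAMES: tuple[str, ...] = (
    "EDAPh_mean", "EDAPh_std", "EDAPh_max", "EDAPh_min", "EDAPh_range", "ncSCR",
    "EDATon_mean", "EDATon_std", "EDATon_max", "EDATon_min", "EDATon_slope",
    "TVSymp_mean", "TVSymp_std", "TVSymp_max", "TVSymp_min", "TVSymp_energy",
    "EDA_LF", "EDA_HF", "EDA_LFHF",
)

#: Default amplitude threshold (μS) for counting a phasic rise as an SCR.
DEFAULT_SCR_THRESHOLD = 0.05

#: Sympathetic-tone band (Hz) for the TVSymp envelope.
TVSYMP_BAND = (0.08, 0.24)

#: Spectral band edges (Hz) for EDA_LF / EDA_HF.
EDA_LF_BAND = (0.045, 0.15)
EDA_HF_BAND = (0.15, 0.25)

#: Tonic-extraction low-pass cutoff (Hz) and order.
TONIC_CUTOFF = 0.05
TONIC_ORDER = 4


@dataclass(frozen=True)
class EdaDecomposition:
    """Additive tonic/phasic split of an EDA signal.

    ``tonic + phasic`` reconstructs the input exactly; ``scr_peaks`` holds
    ``(sample_index, rise_amplitude_uS)`` pairs for detected phasic events.
    """

    tonic: np.ndarray
    phasic: np.ndarray
    fs: float
    scr_peaks: tuple[tuple[int, float], ...] = ()


def decompose(eda: TimeSeries, scr_threshold: float = DEFAULT_SCR_THRESHOLD) -> EdaDecomposition:
    """Split EDA into a slow tonic trend and the fast phasic residual."""
    if eda.n < 2 * eda.fs:
        raise ValueError("EDA record must span at least 2 seconds")
    if np.ptp(eda.values) < 1e-12:
        tonic = eda.values.copy()
    else:
        # subtract the least-squares line before filtering so linear trends
        # pass through exactly (finite-window edge effects otherwise bias
        # the recovered slope), then add it back to the low-pass residual
        t = np.arange(eda.n) / eda.fs
        slope, intercept = np.polyfit(t, eda.values, 1)
        line = intercept + slope * t
        resid = TimeSeries(eda.values - line, fs=eda.fs)
        tonic = line + butterworth(resid, "lowpass", TONIC_CUTOFF, order=TONIC_ORDER).values
    phasic = eda.values - tonic
    count, peaks = detect_nscr(TimeSeries(phasic, fs=eda.fs, channel="phasic"),
                               amp_threshold=scr_threshold)
    return EdaDecomposition(tonic=tonic, phasic=phasic, fs=eda.fs, scr_peaks=tuple(peaks))


def detect_nscr(
    phasic: TimeSeries,
    amp_threshold: float = DEFAULT_SCR_THRESHOLD,
    min_separation_s: float = 1.0,
) -> tuple[int, list[tuple[int, float]]]:
    """Count non-specific SCRs in a phasic trace.

    A local maximum qualifies when its rise from the onset is at least
    ``amp_threshold`` μS, with the onset level taken as the preceding trough
    or the zero baseline, whichever is higher — measuring from the zero
    baseline when the trough undershoots prevents filter-ringing rebounds
    from inflating their apparent amplitude. Peaks closer than
    ``min_separation_s`` are merged (the larger survives). Returns
    ``(count, [(index, rise), ...])``.
    """
    if amp_threshold <= 0:
        raise ValueError("amp_threshold must be positive")
    x = phasic.values
    distance = max(1, int(round(min_separation_s * phasic.fs)))
    peak_idx, _ = signal.find_peaks(x, distance=distance)
    troughs, _ = signal.find_peaks(-x)
    accepted: list[tuple[int, float]] = []
    for p in peak_idx:
        prior = troughs[troughs < p]
        onset = prior[-1] if prior.size else 0
        onset_level = max(float(np.min(x[onset:p + 1])), 0.0)
        rise = x[p] - onset_level
        if rise >= amp_threshold:
            accepted.append((int(p), float(rise)))
    return len(accepted), accepted


def tvsymp_index(eda: TimeSeries) -> tuple[np.ndarray, dict[str, float]]:
    """Time-varying sympathetic-tone index.

    Band-pass the signal to the sympathetic band (0.08-0.24 Hz) and take the
    analytic-signal envelope; summaries are the envelope mean, std, max, min
    and energy (sum of squares / fs, μS²·s) over the window.
    """
    if eda.fs < 2.0:
        raise ValueError("TVSymp needs fs >= 2 Hz")
    min_len = eda.fs / TVSYMP_BAND[0]
    if eda.n < min_len:
        raise DegenerateInputError(
            "window shorter than one cycle of the sympathetic band"
        )
    if np.ptp(eda.values) < 1e-12:
        env = np.zeros(eda.n)
    else:
        band = butterworth(eda, "bandpass", TVSYMP_BAND, order=2).values
        env = np.abs(signal.hilbert(band))
    summary = {
        "TVSymp_mean": float(np.mean(env)),
        "TVSymp_std": float(np.std(env)),
        "TVSymp_max": float(np.max(env)),
        "TVSymp_min": float(np.min(env)),
        "TVSymp_energy": float(np.sum(env**2) / eda.fs),
    }
    return env, summary


def eda_frequency_features(eda: TimeSeries) -> tuple[float, float, float]:
    """Band powers (EDA_LF, EDA_HF) and their ratio from a periodogram of
    the mean-removed signal. A zero HF power yields an infinite ratio."""
    freqs, psd = signal.periodogram(eda.values - np.mean(eda.values), fs=eda.fs)
    lf = _band_power(freqs, psd, EDA_LF_BAND)
    hf = _band_power(freqs, psd, EDA_HF_BAND)
    ratio = lf / hf if hf > 0 else math.inf
    return lf, hf, ratio


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs < band[1])
    if not np.any(mask):
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def traditional_feature_vector(
    eda: TimeSeries,
    scr_threshold: float = DEFAULT_SCR_THRESHOLD,
) -> dict[str, float]:
    """The 19 traditional EDA features for one window, keyed by the frozen
    roster names. Degenerate sub-computations yield NaN markers rather than
    raising, so a pathological window still produces a full-length vector.
    """
    out: dict[str, float] = {}
    dec = decompose(eda, scr_threshold=scr_threshold)
    ph, ton = dec.phasic, dec.tonic
    out["EDAPh_mean"] = float(np.mean(ph))
    out["EDAPh_std"] = float(np.std(ph))
    out["EDAPh_max"] = float(np.max(ph))
    out["EDAPh_min"] = float(np.min(ph))
    out["EDAPh_range"] = out["EDAPh_max"] - out["EDAPh_min"]
    out["ncSCR"] = float(len(dec.scr_peaks))
    out["EDATon_mean"] = float(np.mean(ton))
    out["EDATon_std"] = float(np.std(ton))
    out["EDATon_max"] = float(np.max(ton))
    out["EDATon_min"] = float(np.min(ton))
    t = np.arange(eda.n) / eda.fs
    out["EDATon_slope"] = float(np.polyfit(t, ton, 1)[0]) if eda.n > 1 else 0.0
    try:
        _, tv = tvsymp_index(eda)
        out.update(tv)
    except DegenerateInputError:
        out.update({k: math.nan for k in
                    ("TVSymp_mean", "TVSymp_std", "TVSymp_max", "TVSymp_min", "TVSymp_energy")})
    lf, hf, ratio = eda_frequency_features(eda)
    out["EDA_LF"] = lf
    out["EDA_HF"] = hf
    out["EDA_LFHF"] = ratio
    assert tuple(out) == TRADITIONAL_FEATURE_NAMES
    return out
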