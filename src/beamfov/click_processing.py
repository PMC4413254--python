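"""Click detection and per-click metrics.

Detection is an envelope-threshold detector (Hilbert envelope of the
100-200 kHz band-passed signal, 1 ms dead time).  Per-click metrics use a
fixed 120 us analysis window: 30 us before and 90 us after the envelope
peak, i.e. samples [peak-15, peak+45) at 500 kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt

__all__ = [
    "Click",
    "detect_clicks",
    "envelope",
    "click_energy",
    "snr_gate",
    "centroid_frequency",
    "ici_and_buzz",
    "noise_window_energy",
]

WINDOW_BEFORE_S = 30e-6
WINDOW_AFTER_S = 90e-6
WINDOW_S = WINDOW_BEFORE_S + WINDOW_AFTER_S
DEAD_TIME_S = 1e-3
ANALYSIS_BAND_HZ = (100e3, 200e3)
BUZZ_ICI_S = 13e-3


@dataclass
class Click:
    """One detected emission and its per-channel measurements."""

    id: int
    channel_peak_times: np.ndarray  # s, per channel
    channel_energy: np.ndarray  # EFD dB re 1 uPa^2 s, per channel
    channel_snr: np.ndarray  # dB, per channel
    emission_time: float = math.nan  # filled by localization
    fc: float = math.nan  # Hz
    ici: float = math.nan  # s, to previous click
    is_buzz: bool = False
    meta: dict = field(default_factory=dict)


def _band_sos(fs: float, band=ANALYSIS_BAND_HZ):
    hi = min(band[1], 0.45 * fs)
    return butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")


def envelope(channel: np.ndarray, fs: float, smooth_s: float = 0.0) -> np.ndarray:
    """Magnitude of the analytic signal of the band-passed channel."""
    filtered = sosfiltfilt(_band_sos(fs), np.asarray(channel, dtype=float))
    env = np.abs(hilbert(filtered))
    if smooth_s > 0:
        n = max(1, int(round(smooth_s * fs)))
        env = np.convolve(env, np.ones(n) / n, mode="same")
    return env


def detect_clicks(
    channel: np.ndarray,
    fs: float,
    threshold: float | None = None,
    threshold_factor: float = 10.0,
    dead_time_s: float = DEAD_TIME_S,
) -> np.ndarray:
    """Envelope peak times (s) of candidate clicks.

    ``threshold`` is an absolute envelope level; if None it defaults to
    ``threshold_factor`` times the median envelope (a robust noise scale).
    Peaks closer than the dead time collapse onto the larger one.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty input")
    env = envelope(channel, fs)
    if threshold is None:
        threshold = threshold_factor * float(np.median(env))
    dist = max(1, int(round(dead_time_s * fs)))
    peaks, _ = find_peaks(env, height=threshold, distance=dist)
    return peaks / fs


def click_energy(
    channel: np.ndarray,
    peak_index: int,
    fs: float,
    sensitivity_offset: float = 0.0,
) -> float:
    """EFD (dB re 1 uPa^2 s) over samples [peak-30 us, peak+90 us).

    Pressure squared is integrated over the half-open window and corrected
    by the channel sensitivity offset.
    """
    lo = peak_index - int(round(WINDOW_BEFORE_S * fs))
    hi = peak_index + int(round(WINDOW_AFTER_S * fs))
    if lo < 0 or hi > len(channel):
        raise ValueError("analysis window truncated by record edge")
    e = float(np.sum(np.asarray(channel[lo:hi], dtype=float) ** 2)) / fs
    if e <= 0:
        raise ValueError("zero energy in analysis window")
    return 10.0 * math.log10(e) - sensitivity_offset


def noise_window_energy(
    channel: np.ndarray, peak_index: int, fs: float,
    sensitivity_offset: float = 0.0,
) -> float:
    """EFD of the 120 us window immediately preceding the click window."""
    n = int(round(WINDOW_S * fs))
    start = peak_index - int(round(WINDOW_BEFORE_S * fs)) - n
    return click_energy(channel, start + int(round(WINDOW_BEFORE_S * fs)), fs,
                        sensitivity_offset)


def snr_gate(
    signal_energy_db: np.ndarray,
    noise_energy_db: np.ndarray,
    threshold_db: float,
    dialect: str = "exp1",
) -> bool | np.ndarray:
    """SNR inclusion gate.

    dialect "exp1": signal-to-preceding-noise energy ratio must meet the
    threshold on all channels jointly (returns one bool).  dialect "exp2":
    per-channel gate against the channel noise reference (returns a boolean
    mask).
    """
    sig = np.atleast_1d(np.asarray(signal_energy_db, dtype=float))
    noi = np.broadcast_to(
        np.atleast_1d(np.asarray(noise_energy_db, dtype=float)), sig.shape
    )
    if np.any(~np.isfinite(noi)) and not np.all(np.isneginf(noi)):
        raise ValueError("invalid noise energy")
    ratio = sig - noi
    if dialect == "exp1":
        return bool(np.all(ratio >= threshold_db))
    if dialect == "exp2":
        return ratio >= threshold_db
    raise ValueError(f"unknown snr dialect {dialect!r}")


def centroid_frequency(
    window: np.ndarray, fs: float, band=ANALYSIS_BAND_HZ, nfft: int = 8192
) -> float:
    """Spectral centroid over the analysis band:
    fc = sum(f |X|^2) / sum(|X|^2)."""
    w = np.asarray(window, dtype=float)
    if not np.any(w):
        raise ValueError("all-zero window")
    spec = np.abs(np.fft.rfft(w, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    m = (freqs >= band[0]) & (freqs <= band[1])
    if spec[m].sum() <= 0:
        raise ValueError("no energy in analysis band")
    return float((freqs[m] * spec[m]).sum() / spec[m].sum())


def ici_and_buzz(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-click ICI (s) and buzz labels.

    ici[k] = t[k] - t[k-1]; is_buzz = ici <= 13 ms.  The first click has
    NaN ICI and is labelled by its following interval.
    """
    t = np.asarray(times, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("click times must be strictly increasing")
    ici = np.full(t.shape, np.nan)
    if t.size >= 2:
        ici[1:] = np.diff(t)
    label_src = ici.copy()
    if t.size >= 2:
        label_src[0] = ici[1]
    is_buzz = np.zeros(t.shape, dtype=bool)
    finite = np.isfinite(label_src)
    is_buzz[finite] = label_src[finite] <= BUZZ_ICI_S
    return ici, is_buzz
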