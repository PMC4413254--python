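"""Tag-channel acoustic-scene analysis.

Click-synchronized echograms (stacks of received-envelope rows, one per
outgoing click), delay-to-range conversion at half the sound speed, and
the relative apparent output level (RAOL) series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from beamfov.beam_model import SOUND_SPEED
from beamfov.click_processing import click_energy, envelope

__all__ = ["Echogram", "build_echogram", "delay_to_range", "raol_series"]

DEFAULT_WINDOW_MS = 3.3
ENVELOPE_SMOOTH_S = 20e-6


@dataclass
class Echogram:
    """Click-synchronized envelope stack.

    rows[i, j] is the received envelope ``j / fs`` seconds after click i;
    the delay axis converts to range via ``delay * c / 2``.
    """

    click_times: np.ndarray  # s
    delays: np.ndarray  # s, common delay axis
    rows: np.ndarray  # (n_clicks, n_delays)
    truncated: np.ndarray  # per-row flag: window ran past the record end

    @property
    def ranges(self) -> np.ndarray:
        return delay_to_range(self.delays)


def build_echogram(
    tag_channel: np.ndarray,
    click_times: np.ndarray,
    fs: float,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> Echogram:
    """Envelope segment [0, window] after each click, stacked per click.

    Clicks with ICI shorter than the window simply reappear in following
    rows.  Rows whose window extends past the record end are zero-padded
    and flagged.
    """
    times = np.asarray(click_times, dtype=float)
    if times.size == 0:
        raise ValueError("no click times")
    env = envelope(tag_channel, fs, smooth_s=ENVELOPE_SMOOTH_S)
    n_win = int(round(window_ms * 1e-3 * fs))
    rows = np.zeros((times.size, n_win))
    truncated = np.zeros(times.size, dtype=bool)
    for i, t in enumerate(times):
        start = int(round(t * fs))
        stop = start + n_win
        if stop > len(env):
            truncated[i] = True
            stop = len(env)
        if start < len(env):
            rows[i, : stop - start] = env[start:stop]
    delays = np.arange(n_win) / fs
    return Echogram(times, delays, rows, truncated)


def delay_to_range(delay, sound_speed: float = SOUND_SPEED):
    """Two-way delay (s) to target range (m): delay * c / 2."""
    d = np.asarray(delay, dtype=float)
    if np.any(d < 0):
        raise ValueError("delay must be non-negative")
    out = d * sound_speed / 2.0
    return float(out) if out.ndim == 0 else out


def raol_series(
    tag_channel: np.ndarray, click_times: np.ndarray, fs: float
) -> np.ndarray:
    """Relative apparent output level per click: tag-recorded click EFD
    minus the trial maximum (so the loudest click is 0 dB)."""
    times = np.asarray(click_times, dtype=float)
    if times.size == 0:
        raise ValueError("no clicks")
    env = envelope(tag_channel, fs)
    efd = []
    search = int(round(500e-6 * fs))  # click peak sits shortly after the
    for t in times:                   # nominal emission time
        idx = int(round(t * fs))
        lo = max(idx - 10, 0)
        hi = min(idx + search, len(env))
        peak = lo + int(np.argmax(env[lo:hi]))
        efd.append(click_energy(tag_channel, peak, fs))
    efd = np.asarray(efd)
    return efd - efd.max()
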