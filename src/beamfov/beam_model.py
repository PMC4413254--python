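"""Circular-piston directivity mathematics.

Shared by the simulator and both beam-fitting methods.  A flat circular
piston of radius ``a`` in an infinite baffle radiates with amplitude
directivity 2*J1(ka*sin(theta)) / (ka*sin(theta)); energy directivity is
its square.  Broadband quantities are energy-weighted averages of the
narrowband ratio over a click spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import j1

__all__ = [
    "PistonSpec",
    "piston_directivity",
    "piston_beamwidth",
    "directivity_index",
    "inverse_beamwidth",
    "directivity_db",
]

SOUND_SPEED = 1500.0  # m/s, assumed throughout

#: Root x of (2*J1(x)/x)^2 = 1/2, i.e. the half-power argument.
HALF_POWER_ARG = 1.6163438059863756


@dataclass(frozen=True)
class PistonSpec:
    """Piston aperture plus the narrowband frequency or broadband spectrum
    it radiates.

    ``spectrum`` is a pair (frequencies_hz, energies); energies need not be
    normalized.  Exactly one of ``frequency``/``spectrum`` must be given.
    """

    diameter: float
    frequency: float | None = None
    spectrum: tuple[np.ndarray, np.ndarray] | None = None
    sound_speed: float = SOUND_SPEED

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if (self.frequency is None) == (self.spectrum is None):
            raise ValueError("give exactly one of frequency or spectrum")
        if self.spectrum is not None:
            f, e = self.spectrum
            if np.any(np.asarray(e) < 0) or np.sum(e) <= 0:
                raise ValueError("spectrum energies must be >=0 with positive sum")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def _freqs_weights(self) -> tuple[np.ndarray, np.ndarray]:
        if self.frequency is not None:
            return np.array([self.frequency]), np.array([1.0])
        f, e = self.spectrum
        f = np.asarray(f, dtype=float)
        e = np.asarray(e, dtype=float)
        return f, e / e.sum()


def _energy_ratio(x: np.ndarray) -> np.ndarray:
    """(2*J1(x)/x)^2 with the x -> 0 limit of 1 handled analytically."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = (2.0 * j1(x[nz]) / x[nz]) ** 2
    return out


def piston_directivity(spec: PistonSpec, theta_deg) -> np.ndarray | float:
    """Energy directivity D(theta) in [0, 1] at off-axis angle(s) in degrees.

    Narrowband: [2*J1(ka*sin(theta)) / (ka*sin(theta))]^2.  Broadband: the
    spectrum-energy-weighted average of the narrowband ratio.
    """
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    freqs, w = spec._freqs_weights()
    ka = 2.0 * np.pi * freqs / spec.sound_speed * spec.radius
    x = ka[:, None] * np.sin(np.abs(theta)).ravel()[None, :]
    d = (w[:, None] * _energy_ratio(x)).sum(axis=0)
    d = d.reshape(np.shape(theta))
    return float(d) if np.isscalar(theta_deg) else d


def directivity_db(spec: PistonSpec, theta_deg, floor_db: float = -80.0):
    """10*log10 D(theta), floored to keep nulls finite."""
    d = np.maximum(piston_directivity(spec, theta_deg), 10 ** (floor_db / 10.0))
    return 10.0 * np.log10(d)


def piston_beamwidth(spec: PistonSpec) -> float:
    """Full -3 dB beamwidth in degrees: 2*theta_half with D(theta_half) = 1/2."""
    f = lambda th: piston_directivity(spec, th) - 0.5
    if f(90.0) > 0:
        raise ValueError("beam wider than hemisphere; -3 dB point not reached")
    # D is monotone from the axis to the first crossing; walk out to bracket.
    hi = 0.5
    while f(hi) > 0:
        hi = min(hi * 1.5, 90.0)
    half = brentq(f, hi / 1.5 if hi > 0.5 else 0.0, hi, xtol=1e-10)
    return 2.0 * half


def directivity_index(spec: PistonSpec, n_theta: int = 20001) -> float:
    """DI = 10*log10(4*pi / Int D dOmega), front hemisphere only (back
    radiation taken as zero), by Simpson integration over theta."""
    from scipy.integrate import simpson

    theta = np.linspace(0.0, 90.0, n_theta)
    d = piston_directivity(spec, theta)
    th = np.radians(theta)
    omega = 2.0 * np.pi * simpson(d * np.sin(th), x=th)
    if not np.isfinite(omega) or omega <= 0:
        raise ArithmeticError("directivity integration failed")
    return 10.0 * np.log10(4.0 * np.pi / omega)


def inverse_beamwidth(
    beamwidth_deg: float,
    frequency: float | None = None,
    spectrum=None,
    sound_speed: float = SOUND_SPEED,
    d_min: float = 0.01,
    d_max: float = 0.30,
) -> float:
    """Diameter (m) whose -3 dB beamwidth equals ``beamwidth_deg``.

    Root-finds on the monotone beamwidth-vs-diameter relation within
    [d_min, d_max].
    """

    def err(d: float) -> float:
        spec = PistonSpec(d, frequency=frequency, spectrum=spectrum,
                          sound_speed=sound_speed)
        return piston_beamwidth(spec) - beamwidth_deg

    lo, hi = err(d_min), err(d_max)
    if lo * hi > 0:
        raise ValueError(
            f"beamwidth {beamwidth_deg} deg not achievable for d in "
            f"[{d_min}, {d_max}] m"
        )
    return brentq(err, d_min, d_max, xtol=1e-7)
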