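"""Source localization and bearing from hydrophone arrival-time differences.

Hyperbolic range-difference equations are solved by nonlinear least
squares at c = 1500 m/s.  Linear-array fixes are constrained to the
half-space y > 0 and the array's horizontal plane z = 0 (the left/right
and vertical ambiguities of a line array).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from beamfov.beam_model import SOUND_SPEED
from beamfov.geometry import ArrayGeometry

__all__ = [
    "SourceFix",
    "tdoa_estimate",
    "refine_peak_time",
    "localize_source",
    "bearing_to_centre",
]


@dataclass
class SourceFix:
    """Localized source: position, range/bearing to the array centre and
    the rms TDOA misfit of the solution."""

    position: np.ndarray
    range_to_array_centre: float
    azimuth: float  # deg, horizontal angle off the array normal (+y)
    elevation: float  # deg, vertical angle
    residual: float  # s, rms TDOA misfit
    reference_channel: int = 0
    assumptions: dict = field(default_factory=dict)


def refine_peak_time(env: np.ndarray, peak_index: int, fs: float) -> float:
    """Sub-sample envelope peak time by a three-point parabola."""
    if 0 < peak_index < len(env) - 1:
        y0, y1, y2 = env[peak_index - 1 : peak_index + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1:
                return (peak_index + delta) / fs
    return peak_index / fs


def tdoa_estimate(
    peak_times: np.ndarray,
    geometry: ArrayGeometry,
    reference: int | None = None,
    snr: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Arrival-time differences relative to a reference channel.

    The reference is the highest-SNR channel when ``snr`` is given, else
    the earliest arrival.  Returns (tdoas, reference index); the reference
    entry is zero.
    """
    t = np.asarray(peak_times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two channels for TDOAs")
    if reference is None:
        reference = int(np.argmax(snr)) if snr is not None else int(np.argmin(t))
    return t - t[reference], reference


def localize_source(
    tdoas: np.ndarray,
    geometry: ArrayGeometry,
    reference: int = 0,
    arrival_time: float | None = None,
    sound_speed: float = SOUND_SPEED,
    residual_tol: float = 5e-6,
) -> SourceFix:
    """Nonlinear least-squares fix from range differences.

    The solver starts at the geometry's target position.  For the linear
    array the fix is constrained to z = 0 and y > 0.  ``arrival_time`` (s,
    on the reference channel) back-computes the emission time stored in
    ``assumptions['emission_time']``.
    """
    tdoas = np.asarray(tdoas, dtype=float)
    pos = geometry.positions
    if tdoas.shape[0] != pos.shape[0]:
        raise ValueError("one TDOA per hydrophone required")
    if pos.shape[0] < 3:
        raise ValueError("need at least three channels to localize")
    planar = geometry.label == "linear"
    x0 = geometry.target.copy()

    def unpack(p):
        if planar:
            return np.array([p[0], p[1], 0.0])
        return p

    rdiff = tdoas * sound_speed

    def resid(p):
        # residuals scaled to metres so solver tolerances are meaningful;
        # centred (mean-referenced) so no single channel biases the fit
        s = unpack(p)
        r = np.linalg.norm(pos - s[None, :], axis=1)
        return (r - r.mean()) - (rdiff - rdiff.mean())

    far = 100.0  # m, well beyond any recording range
    if planar:
        res = least_squares(
            resid, x0[:2], bounds=([-far, 1e-3], [far, far]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    else:
        res = least_squares(
            resid, x0, bounds=([-far, 1e-3, -far], [far] * 3),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    if not res.success:
        raise RuntimeError("localization did not converge")
    s = unpack(res.x)
    rms = float(np.sqrt(np.mean(res.fun**2))) / sound_speed
    centre = geometry.centre
    rel = s - centre
    rng = float(np.linalg.norm(rel))
    az, el = _decompose_bearing(rel)
    assumptions = {"planar_constraint": planar, "dilution_flag": rms > residual_tol}
    if arrival_time is not None:
        rref = float(np.linalg.norm(pos[reference] - s))
        assumptions["emission_time"] = arrival_time - rref / sound_speed
    return SourceFix(
        position=s,
        range_to_array_centre=rng,
        azimuth=az,
        elevation=el,
        residual=rms,
        reference_channel=reference,
        assumptions=assumptions,
    )


def _decompose_bearing(rel: np.ndarray) -> tuple[float, float]:
    if np.linalg.norm(rel) < 1e-9:
        raise ValueError("fix at the array centre has no bearing")
    az = math.degrees(math.atan2(rel[0], rel[1]))
    el = math.degrees(math.atan2(rel[2], math.hypot(rel[0], rel[1])))
    return az, el


def bearing_to_centre(fix: SourceFix, geometry: ArrayGeometry) -> tuple[float, float]:
    """(azimuth, elevation) in degrees of the fix, seen from the array
    centre relative to the array normal (+y toward the animal)."""
    return _decompose_bearing(np.asarray(fix.position) - geometry.centre)
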