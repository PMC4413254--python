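"""Linear-array beam estimation: apparent-source-level radiation pattern
and a one-dimensional piston fit.

Per-hydrophone apparent source levels (spherical-spreading back-
calculation) are plotted against angle; the peak is refined as the vertex
of the second-order Lagrange polynomial through the loudest hydrophone
and its two neighbours, the pattern re-expressed as off-axis angle from
that vertex and resampled onto a 0.1 degree grid, then fitted (in dB) by
the piston directivity over the shared candidate-diameter grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from beamfov import beam_model
from beamfov.beam_model import PistonSpec
from beamfov.beam_star import candidate_diameters
from beamfov.geometry import ArrayGeometry
from beamfov.localization import SourceFix

__all__ = [
    "RadiationPattern",
    "LinearPistonFit",
    "apparent_source_level",
    "lagrange_vertex",
    "build_radiation_pattern",
    "fit_piston_to_pattern",
]

PATTERN_GRID_DEG = 0.1
SNR_GATE_DB = 6.0


@dataclass
class RadiationPattern:
    """Off-axis ASL pattern on a 0.1 degree grid."""

    angles: np.ndarray  # deg, relative to the refined on-axis direction
    asl: np.ndarray  # dB re 1 uPa^2 s @ 1 m
    peak_angle: float  # deg, vertex position in raw hydrophone angles
    peak_asl: float  # dB
    raw_angles: np.ndarray = field(default=None)
    raw_asl: np.ndarray = field(default=None)


@dataclass
class LinearPistonFit:
    """Piston fit to a 1D radiation pattern."""

    best_diameter: float  # m
    beamwidth_deg: float
    directivity_index_db: float
    fit_error: float
    lower_bounded: bool = False  # pattern never dropped 3 dB below peak


def apparent_source_level(received_efd_db, range_m) -> float | np.ndarray:
    """ASL = received EFD + 20*log10(range / 1 m); spherical spreading,
    no absorption term."""
    r = np.asarray(range_m, dtype=float)
    if np.any(r <= 0):
        raise ValueError("range must be positive")
    out = np.asarray(received_efd_db, dtype=float) + 20.0 * np.log10(r)
    return float(out) if out.ndim == 0 else out


def lagrange_vertex(
    angles: np.ndarray, levels: np.ndarray
) -> tuple[float, float]:
    """Vertex of the second-order Lagrange polynomial through three
    (angle, dB) points; returns (angle, level)."""
    x = np.asarray(angles, dtype=float)
    y = np.asarray(levels, dtype=float)
    if x.shape != (3,) or y.shape != (3,):
        raise ValueError("exactly three points required")
    coeffs = np.polyfit(x, y, 2)
    a, b, _ = coeffs
    if a >= 0:
        # no interior maximum; fall back to the middle sample
        return float(x[1]), float(y[1])
    xv = -b / (2 * a)
    return float(xv), float(np.polyval(coeffs, xv))


def build_radiation_pattern(
    channel_efd_db: np.ndarray,
    fix: SourceFix,
    geometry: ArrayGeometry,
    grid_deg: float = PATTERN_GRID_DEG,
) -> RadiationPattern:
    """ASL-vs-angle pattern for one click from a localized source.

    Angles are signed along the array axis in the z = 0 plane, seen from
    the source.  Rejects clicks whose ASL peak falls on an outermost
    hydrophone (the vertex would be unconstrained).
    """
    efd = np.asarray(channel_efd_db, dtype=float)
    pos = geometry.positions
    s = np.asarray(fix.position, dtype=float)
    vec = pos - s[None, :]
    r = np.linalg.norm(vec, axis=1)
    asl = apparent_source_level(efd, r)
    # signed angle of each hydrophone about the source->centre direction
    centre_dir = geometry.centre - s
    ang_centre = math.atan2(centre_dir[0], -centre_dir[1])
    ang = np.degrees(np.arctan2(vec[:, 0], -vec[:, 1]) - ang_centre)
    order = np.argsort(ang)
    ang, asl = ang[order], asl[order]
    peak = int(np.argmax(asl))
    if peak in (0, len(asl) - 1):
        raise ValueError("ASL peak on an outermost hydrophone; click rejected")
    vx, vy = lagrange_vertex(ang[peak - 1 : peak + 2], asl[peak - 1 : peak + 2])
    off = ang - vx
    grid = np.arange(math.ceil(off.min() / grid_deg), math.floor(off.max() / grid_deg) + 1)
    grid = grid * grid_deg
    # include the vertex sample so the interpolated pattern peaks there
    pts_x = np.concatenate([off, [0.0]])
    pts_y = np.concatenate([asl, [vy]])
    srt = np.argsort(pts_x)
    resampled = np.interp(grid, pts_x[srt], pts_y[srt])
    return RadiationPattern(
        angles=grid,
        asl=resampled,
        peak_angle=vx,
        peak_asl=vy,
        raw_angles=off,
        raw_asl=asl,
    )


def fit_piston_to_pattern(
    pattern: RadiationPattern,
    spectrum=None,
    frequency: float | None = None,
    diameters: np.ndarray | None = None,
) -> LinearPistonFit:
    """Least-squares fit (in dB) of the piston directivity to the pattern,
    centred on the vertex, over the candidate-diameter grid.

    The fit scores the measured samples (per-hydrophone ASLs at their raw
    off-axis angles, when available); the 0.1 degree resampled grid is an
    export product whose linear interpolation between widely spaced
    hydrophones would otherwise be fitted instead of the data.
    """
    if (frequency is None) == (spectrum is None):
        raise ValueError("give exactly one of frequency or spectrum")
    if diameters is None:
        diameters = candidate_diameters()
    if pattern.raw_angles is not None:
        ang, asl = pattern.raw_angles, pattern.raw_asl
    else:
        ang, asl = pattern.angles, pattern.asl
    # keep samples within 30 dB of the peak: dB residuals near pattern
    # nulls are hypersensitive to the candidate diameter and would swamp
    # the main-lobe fit
    sel = asl >= asl.max() - 30.0
    ang, asl = ang[sel], asl[sel]
    lower_bounded = asl.min() > pattern.peak_asl - 3.0
    # amplitude is a free (closed-form) parameter per candidate: with
    # sparse angular sampling the parabola vertex underestimates the true
    # on-axis level, so anchoring to it would bias the aperture
    errs = np.empty(len(diameters))
    for i, d in enumerate(diameters):
        spec = PistonSpec(d, frequency=frequency, spectrum=spectrum)
        shape = beam_model.directivity_db(spec, ang)
        amp = float(np.mean(asl - shape))
        errs[i] = float(np.sum((asl - amp - shape) ** 2))
    best = int(np.argmin(errs))
    spec = PistonSpec(float(diameters[best]), frequency=frequency, spectrum=spectrum)
    return LinearPistonFit(
        best_diameter=float(diameters[best]),
        beamwidth_deg=beam_model.piston_beamwidth(spec),
        directivity_index_db=beam_model.directivity_index(spec),
        fit_error=float(errs[best]),
        lower_bounded=lower_bounded,
    )
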