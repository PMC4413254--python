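"""Star-array beam estimation: channel gating, energy-surface fitting,
beam-axis estimation and the Monte-Carlo piston fit.

The per-click chain is: (1) keep channels whose received level exceeds the
channel noise by >= 14 dB; (2) grid the per-channel click energies over
the array plane (0.5 cm cells, restricted to the disc subtending +-20 deg
at the emission range) and take the surface peak as the beam axis; (3) fit
candidate pistons (diameters 1/3 to 3 times 8.3 cm in 0.1 cm steps) aimed
at that axis from the source position, anchored to the click measured on
the axis-nearest hydrophone, and keep the least-squares-best diameter.
Fits with R^2 <= 0.8 are excluded from final analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from beamfov import beam_model
from beamfov._gridfit import gridfit
from beamfov.beam_model import PistonSpec, _energy_ratio
from beamfov.geometry import ArrayGeometry

__all__ = [
    "PistonFit",
    "EnergySurface",
    "candidate_diameters",
    "select_channels",
    "fit_energy_surface",
    "fit_piston_star",
    "apply_inclusion_criteria",
]

CHANNEL_GATE_DB = 14.0
GRID_CELL_M = 0.005
MAX_HALF_ANGLE_DEG = 20.0
R2_GATE = 0.8
LSE_GATE = 0.2  # alternative gate on the fit error itself; off by default
SPREAD_FRACTION = 0.05
REFERENCE_DIAMETER_M = 0.083

#: Inclusion bounds: bearing (deg, both axes) and axis displacement (cm).
BEARING_BOUND_DEG = 15.0
DISPLACEMENT_BOUNDS_CM = {
    ("large", None): 12.0,
    ("small", "pre_buzz"): 8.0,
    ("small", "buzz"): 6.0,
}


def candidate_diameters(
    reference: float = REFERENCE_DIAMETER_M, step: float = 0.001
) -> np.ndarray:
    """Candidate piston diameters (m): 1/3 to 3x the reference aperture in
    0.1 cm increments (grid start rounded up to the step)."""
    lo = math.ceil(reference / 3.0 / step - 1e-9) * step
    hi = reference * 3.0
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


@dataclass
class EnergySurface:
    """Gridded click-energy surface over the array plane."""

    xnodes: np.ndarray  # m
    znodes: np.ndarray  # m
    values: np.ndarray  # dB, shape (len(znodes), len(xnodes))
    axis_position: tuple[float, float]  # (x, z) m
    on_boundary: bool


@dataclass
class PistonFit:
    """Result of the Monte-Carlo piston fit for one click."""

    axis_position: tuple[float, float]  # (x, z) cm on the array plane
    best_diameter: float  # m
    beamwidth_deg: float
    r_squared: float
    lse: float
    spread_deg: tuple[float, float]
    n_channels: int
    included: bool = True
    reasons: list[str] = field(default_factory=list)
    error_curve: np.ndarray | None = None
    diameters: np.ndarray | None = None


def select_channels(
    peak_level_db: np.ndarray,
    noise_level_db: np.ndarray | float,
    gate_db: float = CHANNEL_GATE_DB,
    min_channels: int = 5,
) -> np.ndarray:
    """Boolean mask of channels whose received level exceeds the channel
    noise reference by at least ``gate_db``."""
    lev = np.asarray(peak_level_db, dtype=float)
    noi = np.broadcast_to(np.asarray(noise_level_db, dtype=float), lev.shape)
    mask = lev - noi >= gate_db
    if mask.sum() < min_channels:
        raise ValueError(
            f"only {int(mask.sum())} channels pass the {gate_db} dB gate; "
            f">= {min_channels} required"
        )
    return mask


def _argmax_towards_centre(
    values: np.ndarray, xn: np.ndarray, zn: np.ndarray, bbox=None
):
    """Argmax of the surface, restricted to the data bounding box (the
    axis must lie within the sampled area; smoothed surfaces extrapolate
    linearly and can rise spuriously beyond the last hydrophone).  Ties
    break toward the array centre."""
    work = values.copy()
    if bbox is not None:
        x0, x1, z0, z1 = bbox
        keep_x = (xn >= x0 - 1e-9) & (xn <= x1 + 1e-9)
        keep_z = (zn >= z0 - 1e-9) & (zn <= z1 + 1e-9)
        if keep_x.any() and keep_z.any():
            work[~keep_z, :] = -np.inf
            work[:, ~keep_x] = -np.inf
    flat = work.ravel()
    best = flat.max()
    tied = np.flatnonzero(flat >= best - 1e-12)
    if tied.size == 1:
        k = tied[0]
    else:
        jz, ix = np.unravel_index(tied, values.shape)
        rad = np.hypot(xn[ix], zn[jz])
        k = tied[int(np.argmin(rad))]
    jz, ix = np.unravel_index(k, values.shape)
    return int(ix), int(jz)


def _grid_once(x, z, v, half_extent, cell, centre=(0.0, 0.0), smoothness=1.0):
    cx, cz = centre
    nx = max(2, int(math.ceil(2 * half_extent / cell)) + 1)
    xn = cx + (np.arange(nx) - (nx - 1) / 2) * cell
    zn = cz + (np.arange(nx) - (nx - 1) / 2) * cell
    inside = (
        (x >= xn[0]) & (x <= xn[-1]) & (z >= zn[0]) & (z <= zn[-1])
    )
    if inside.sum() < 3:
        raise ValueError("too few gated channels inside the gridding region")
    vals = gridfit(x[inside], z[inside], v[inside], xn, zn, smoothness)
    return xn, zn, vals


def fit_energy_surface(
    channel_energies_db: np.ndarray,
    geometry: ArrayGeometry,
    emission_range: float,
    mask: np.ndarray | None = None,
    cell: float = GRID_CELL_M,
    max_half_angle_deg: float = MAX_HALF_ANGLE_DEG,
    smoothness: float = 1.0,
) -> EnergySurface:
    """Grid gated per-channel click energies over the array plane and take
    the surface peak as the beam axis.

    The region is the disc subtending ``max_half_angle_deg`` at the
    emission range, clipped to the gated-data extent.  Large regions are
    solved in two stages (coarse pass, then a 0.5 cm pass around the
    coarse peak) so the argmax is always on the 0.5 cm lattice.
    """
    v = np.asarray(channel_energies_db, dtype=float)
    pos = geometry.positions
    if mask is None:
        mask = np.ones(len(v), dtype=bool)
    x, z, v = pos[mask, 0], pos[mask, 2], v[mask]
    if len(v) < 5:
        raise ValueError("need >= 5 gated channels for a surface fit")
    disc = emission_range * math.tan(math.radians(max_half_angle_deg))
    data_extent = float(np.max(np.hypot(x, z)))
    half = min(disc, data_extent + 2 * cell)
    half = max(half, 4 * cell)

    bbox = (float(x.min()), float(x.max()), float(z.min()), float(z.max()))
    max_direct = 80  # direct solve up to ~80x80 nodes; larger goes two-stage
    coarse_nodes = 48
    if 2 * half / cell + 1 <= max_direct:
        xn, zn, vals = _grid_once(x, z, v, half, cell, smoothness=smoothness)
    else:
        coarse = 2 * half / coarse_nodes
        xn_c, zn_c, vals_c = _grid_once(x, z, v, half, coarse, smoothness=smoothness)
        ix, jz = _argmax_towards_centre(vals_c, xn_c, zn_c, bbox)
        cx = round(xn_c[ix] / cell) * cell
        cz = round(zn_c[jz] / cell) * cell
        # window wide enough to enclose a ring of neighbouring hydrophones,
        # otherwise the local solve is unconstrained between data points
        win = max(0.20, 2.5 * coarse)
        xn, zn, vals = _grid_once(x, z, v, win, cell, centre=(cx, cz),
                                  smoothness=smoothness)
    ix, jz = _argmax_towards_centre(vals, xn, zn, bbox)
    on_boundary = ix in (0, len(xn) - 1) or jz in (0, len(zn) - 1)
    # patch scaled with range: the beam footprint (and hence the scale over
    # which the bump top is quadratic) grows with emission range
    patch_m = float(np.interp(emission_range, [0.0, 2.0, 7.0], [0.04, 0.04, 0.08]))
    ax, az = _refine_peak(vals, xn, zn, ix, jz, patch_m)
    return EnergySurface(xn, zn, vals, (ax, az), on_boundary)


def _refine_peak(vals, xn, zn, ix, jz, half_width_m):
    """Sub-cell peak of the fitted surface: least-squares quadratic vertex
    over a patch around the argmax, clamped to the patch.

    Interpolation wiggle between hydrophones displaces the lattice argmax
    by up to ~1 cm; a quadratic fitted across the smooth bump top averages
    it out (same reasoning as the linear-array Lagrange vertex).
    """
    cell = float(xn[1] - xn[0])
    k = int(round(half_width_m / cell))
    k = min(k, ix, len(xn) - 1 - ix, jz, len(zn) - 1 - jz)
    if k < 1:
        return float(xn[ix]), float(zn[jz])
    patch = vals[jz - k : jz + k + 1, ix - k : ix + k + 1]
    g = np.arange(-k, k + 1, dtype=float)
    gx, gz = np.meshgrid(g, g)
    a = np.column_stack([
        np.ones(patch.size), gx.ravel(), gz.ravel(),
        gx.ravel() ** 2, gx.ravel() * gz.ravel(), gz.ravel() ** 2,
    ])
    c = np.linalg.lstsq(a, patch.ravel(), rcond=None)[0]
    h = np.array([[2 * c[3], c[4]], [c[4], 2 * c[5]]])
    if np.linalg.det(h) <= 0 or h[0, 0] >= 0:  # not a maximum
        return float(xn[ix]), float(zn[jz])
    off = np.clip(np.linalg.solve(h, -np.array([c[1], c[2]])), -k, k)
    return float(xn[ix] + off[0] * cell), float(zn[jz] + off[1] * cell)


def fit_piston_star(
    channel_energies_db: np.ndarray,
    geometry: ArrayGeometry,
    axis_position: tuple[float, float],
    source_position: np.ndarray,
    spectrum=None,
    frequency: float | None = None,
    mask: np.ndarray | None = None,
    diameters: np.ndarray | None = None,
    keep_error_curve: bool = False,
) -> PistonFit:
    """Monte-Carlo piston fit for one click.

    For every candidate diameter, predict the energy at each gated
    hydrophone from a piston at the source position aimed at the axis
    point, anchored to the click measured on the axis-nearest hydrophone;
    score by the least-square error on dB energies.
    """
    v = np.asarray(channel_energies_db, dtype=float)
    pos = geometry.positions
    if mask is None:
        mask = np.ones(len(v), dtype=bool)
    pos, v = pos[mask], v[mask]
    if len(v) < 5:
        raise ValueError("need >= 5 gated channels for a piston fit")
    if diameters is None:
        diameters = candidate_diameters()
    if (frequency is None) == (spectrum is None):
        raise ValueError("give exactly one of frequency or spectrum")

    s = np.asarray(source_position, dtype=float)
    axis3 = np.array([axis_position[0], 0.0, axis_position[1]])
    u = axis3 - s
    u = u / np.linalg.norm(u)
    vec = pos - s[None, :]
    r = np.linalg.norm(vec, axis=1)
    theta = np.degrees(np.arccos(np.clip(vec @ u / r, -1.0, 1.0)))
    anchor = int(np.argmin(np.hypot(pos[:, 0] - axis3[0], pos[:, 2] - axis3[2])))

    # directivity in dB for every (candidate, channel), vectorized
    if spectrum is not None:
        freqs = np.asarray(spectrum[0], dtype=float)
        w = np.asarray(spectrum[1], dtype=float)
        w = w / w.sum()
    else:
        freqs, w = np.array([frequency]), np.array([1.0])
    ka = 2.0 * np.pi * freqs / beam_model.SOUND_SPEED * (diameters[:, None] / 2.0)
    xarg = ka[:, :, None] * np.sin(np.radians(theta))[None, None, :]
    dmat = (w[None, :, None] * _energy_ratio(xarg)).sum(axis=1)
    ddb = 10.0 * np.log10(np.maximum(dmat, 1e-8))
    spread_db = -20.0 * np.log10(r / r[anchor])
    pred = v[anchor] + (ddb - ddb[:, anchor][:, None]) + spread_db[None, :]
    lse = np.sum((v[None, :] - pred) ** 2, axis=1)

    def bw_of(d: float) -> float:
        return beam_model.piston_beamwidth(
            PistonSpec(d, frequency=frequency, spectrum=spectrum)
        )

    best = int(np.argmin(lse))
    sstot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - lse[best] / sstot if sstot > 0 else float("nan")
    lo, hi = lse.min(), lse.max()
    reasons: list[str] = []
    if hi - lo <= 1e-12:
        reasons.append("flat_error_curve")
        sel = np.ones(len(diameters), dtype=bool)
    else:
        thr = lo + SPREAD_FRACTION * (hi - lo)
        sel = lse <= thr
    # beamwidth is monotone decreasing in diameter, so the spread interval
    # is set by the extreme selected diameters
    spread = (float(bw_of(diameters[sel].max())), float(bw_of(diameters[sel].min())))
    included = True
    if not (r2 > R2_GATE):
        included = False
        reasons.append("r_squared_gate")
    return PistonFit(
        axis_position=(axis_position[0] * 100.0, axis_position[1] * 100.0),
        best_diameter=float(diameters[best]),
        beamwidth_deg=float(bw_of(diameters[best])),
        r_squared=float(r2),
        lse=float(lse[best]),
        spread_deg=spread,
        n_channels=int(len(v)),
        included=included,
        reasons=reasons,
        error_curve=lse if keep_error_curve else None,
        diameters=diameters if keep_error_curve else None,
    )


def apply_inclusion_criteria(
    fit: PistonFit,
    azimuth_deg: float,
    elevation_deg: float,
    config: str,
    phase: str | None = None,
    bearing_bound_deg: float = BEARING_BOUND_DEG,
) -> tuple[bool, list[str]]:
    """Inclusion per bearing and axis-displacement bounds.

    config "large" uses +-12 cm; "small" uses +-8 cm up to 1 s before buzz
    (phase "pre_buzz") and +-6 cm from 1 s before buzz onward (phase
    "buzz").  Missing phase on the small array applies the conservative
    +-6 cm bound.
    """
    reasons = []
    if abs(azimuth_deg) > bearing_bound_deg or abs(elevation_deg) > bearing_bound_deg:
        reasons.append("bearing_bound")
    if config == "large":
        bound = DISPLACEMENT_BOUNDS_CM[("large", None)]
    elif config == "small":
        key = phase if phase in ("pre_buzz", "buzz") else "buzz"
        bound = DISPLACEMENT_BOUNDS_CM[("small", key)]
    else:
        raise ValueError(f"unknown array config {config!r}")
    if math.hypot(*fit.axis_position) > bound:
        reasons.append("axis_displacement_bound")
    ok = not reasons
    return ok, reasons
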