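"""Array geometries and coordinate conventions.

Conventions: origin at the array centre; +y points from the array toward
the approaching animal; x is horizontal in the array plane; z is vertical.
The linear array lies along x at z = 0; star arrays lie in the x-z plane.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Hydrophone",
    "ArrayGeometry",
    "build_linear_array",
    "build_star_array",
    "effective_angular_resolution",
    "STAR_AXIS_OFFSETS_M",
    "STAR_DIAGONAL_OFFSETS_M",
]

#: Cumulative hydrophone offsets (m) from the array centre along the four
#: axis-aligned star arms, per configuration.
STAR_AXIS_OFFSETS_M = {
    "large": (0.05, 0.15, 0.30, 0.50, 0.75, 1.05),
    "small": (0.05, 0.10, 0.15, 0.30, 0.55),
}

#: Cumulative offsets (m) along the four diagonal star arms.  Values carry
#: 1 mm rounding and correspond to points of a 5 cm mesh grid.
STAR_DIAGONAL_OFFSETS_M = {
    "large": (0.141, 0.282, 0.494, 0.777, 1.131),
    "small": (0.071, 0.142, 0.283, 0.495),
}

#: Default target stand-off (m) in front of the array centre (+y).
STAR_TARGET_STANDOFF_M = {"large": 0.05, "small": 0.40}

#: Physical channel count of the star arrays; arm positions are padded with
#: auxiliary mesh hydrophones up to this count.
STAR_CHANNEL_COUNT = 48

_MESH_PITCH_M = 0.05


@dataclass(frozen=True)
class Hydrophone:
    """One array element: integer id, position (m) and a relative
    sensitivity offset (dB) subtracted from its received levels."""

    id: int
    position: tuple[float, float, float]
    sensitivity_offset: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.sensitivity_offset):
            raise ValueError("sensitivity_offset must be finite")
        if len(self.position) != 3:
            raise ValueError("position must be a 3-vector")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class ArrayGeometry:
    """A set of hydrophones plus the target position they surround."""

    hydrophones: list[Hydrophone]
    target_position: tuple[float, float, float]
    label: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.hydrophones) < 2:
            raise ValueError("an array needs at least two hydrophones")
        ids = [h.id for h in self.hydrophones]
        if len(set(ids)) != len(ids):
            raise ValueError("hydrophone ids must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.hydrophones)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) hydrophone positions in metres."""
        return np.stack([h.xyz for h in self.hydrophones])

    @property
    def sensitivities(self) -> np.ndarray:
        return np.array([h.sensitivity_offset for h in self.hydrophones])

    @property
    def centre(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def target(self) -> np.ndarray:
        return np.asarray(self.target_position, dtype=float)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "hydrophones": [
                {
                    "id": h.id,
                    "xyz_m": list(h.position),
                    "sens_db": h.sensitivity_offset,
                }
                for h in self.hydrophones
            ],
            "target_xyz_m": list(self.target_position),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayGeometry":
        phones = [
            Hydrophone(int(h["id"]), tuple(h["xyz_m"]), float(h.get("sens_db", 0.0)))
            for h in d["hydrophones"]
        ]
        return cls(phones, tuple(d["target_xyz_m"]), d["label"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ArrayGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_linear_array(
    target_range: float = 3.0, sensitivities: Sequence[float] | None = None
) -> ArrayGeometry:
    """Horizontal 8-element linear array, 0.6 m spacing, centred on the
    origin, with the target on the +y axis (default 3 m)."""
    xs = np.arange(8) * 0.6 - 2.1
    if sensitivities is None:
        sensitivities = [0.0] * 8
    phones = [
        Hydrophone(i, (float(x), 0.0, 0.0), float(s))
        for i, (x, s) in enumerate(zip(xs, sensitivities))
    ]
    return ArrayGeometry(phones, (0.0, float(target_range), 0.0), "linear")


def _mesh_pad_positions(
    occupied: np.ndarray, n_needed: int, pitch: float = _MESH_PITCH_M
) -> list[tuple[float, float]]:
    """Vacant 5 cm mesh points nearest the centre (radius, then angle)."""
    pads: list[tuple[float, float, float, float]] = []
    for i in range(-4, 5):
        for j in range(-4, 5):
            x, z = i * pitch, j * pitch
            r = math.hypot(x, z)
            if r < 1e-9:
                continue
            d = np.hypot(occupied[:, 0] - x, occupied[:, 1] - z)
            if d.min() < 2e-3:
                continue
            ang = math.atan2(z, x) % (2 * math.pi)
            pads.append((r, ang, x, z))
    pads.sort()
    if len(pads) < n_needed:
        raise RuntimeError("mesh padding exhausted")
    return [(x, z) for _, _, x, z in pads[:n_needed]]


def build_star_array(
    config: str,
    target_standoff: float | None = None,
    sensitivities: Sequence[float] | None = None,
    pad_to: int | None = STAR_CHANNEL_COUNT,
) -> ArrayGeometry:
    """48-channel star array in the x-z plane: a centre hydrophone, four
    axis-aligned arms, four diagonal arms, and auxiliary mesh hydrophones
    filling the channel count.

    Parameters
    ----------
    config : {"large", "small"}
        Arm spacing schedule: "large" for long-range trials, "small" for
        the tighter short-range layout.
    target_standoff : float, optional
        Target distance in front of the centre (m); defaults to 0.05
        (large) or 0.40 (small).
    pad_to : int or None
        Total channel count to pad to with vacant mesh positions
        (default 48); ``None`` keeps only centre + arms.
    """
    if config not in STAR_AXIS_OFFSETS_M:
        raise ValueError(f"unknown star configuration {config!r}")
    axis_off = STAR_AXIS_OFFSETS_M[config]
    diag_off = STAR_DIAGONAL_OFFSETS_M[config]
    if target_standoff is None:
        target_standoff = STAR_TARGET_STANDOFF_M[config]

    inv2 = 1.0 / math.sqrt(2.0)
    axis_dirs = [(1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0)]
    diag_dirs = [(inv2, inv2), (-inv2, inv2), (-inv2, -inv2), (inv2, -inv2)]

    xz: list[tuple[float, float]] = [(0.0, 0.0)]
    for ux, uz in axis_dirs:
        xz.extend((round(ux * o, 4), round(uz * o, 4)) for o in axis_off)
    for ux, uz in diag_dirs:
        xz.extend((round(ux * o, 4), round(uz * o, 4)) for o in diag_off)

    if pad_to is not None:
        if pad_to < len(xz):
            raise ValueError(f"pad_to={pad_to} below arm hydrophone count {len(xz)}")
        xz.extend(_mesh_pad_positions(np.array(xz), pad_to - len(xz)))

    if sensitivities is None:
        sensitivities = [0.0] * len(xz)
    phones = [
        Hydrophone(i, (float(x), 0.0, float(z)), float(s))
        for i, ((x, z), s) in enumerate(zip(xz, sensitivities))
    ]
    label = "star_large" if config == "large" else "star_small"
    return ArrayGeometry(phones, (0.0, float(target_standoff), 0.0), label)


def effective_angular_resolution(spacing: float, range_: float) -> float:
    """Finest resolvable angle (degrees): atan(spacing / range)."""
    if spacing <= 0 or range_ <= 0:
        raise ValueError("spacing and range must be positive")
    return math.degrees(math.atan(spacing / range_))
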