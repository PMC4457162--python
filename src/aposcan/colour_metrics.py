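"""Per-surface signal attributes: tetrahedral position, saturation,
luminance and pattern area.

Tetrahedron convention (fixed, documented): regular tetrahedron centred at
the achromatic origin with circumradius 0.75, UV vertex on +z, SW vertex in
the +x half of the z = -0.25 plane, MW and LW at +/-120 degrees around z.
A fully saturated single-cone stimulus therefore has saturation 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .types import ConeCatch

CIRCUMRADIUS = 0.75

_rxy = CIRCUMRADIUS * 2.0 * np.sqrt(2.0) / 3.0
#: vertices in canonical (UV, SW, MW, LW) order
TETRA_VERTICES = np.array([
    [0.0, 0.0, CIRCUMRADIUS],
    [_rxy, 0.0, -CIRCUMRADIUS / 3.0],
    [_rxy * np.cos(2 * np.pi / 3), _rxy * np.sin(2 * np.pi / 3),
     -CIRCUMRADIUS / 3.0],
    [_rxy * np.cos(4 * np.pi / 3), _rxy * np.sin(4 * np.pi / 3),
     -CIRCUMRADIUS / 3.0],
])


@dataclass(frozen=True)
class TetraPoint:
    """A colour's position in tetrahedral space plus its relative catches."""

    x: float
    y: float
    z: float
    u: float
    s: float
    m: float
    l: float

    def __post_init__(self) -> None:
        rel = np.array([self.u, self.s, self.m, self.l])
        if np.any(rel < -1e-12):
            raise ValueError("relative catches must be non-negative")
        if abs(rel.sum() - 1.0) > 1e-9:
            raise ValueError("relative catches must sum to 1")

    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def to_tetrahedral(catch: ConeCatch) -> TetraPoint:
    """Map a cone catch to its point in the tetrahedral colour space."""
    q = catch.singles()
    if np.any(q < 0):
        raise ValueError("cone catches must be non-negative")
    total = q.sum()
    if total <= 0:
        raise ValueError("total single-cone catch must be positive")
    rel = q / total
    pos = rel @ TETRA_VERTICES
    return TetraPoint(*(float(v) for v in pos), *(float(v) for v in rel))


def saturation(point: TetraPoint) -> float:
    """Euclidean distance from the achromatic centre; <= 0.75 by geometry."""
    return float(np.linalg.norm(point.xyz()))


def luminance(catch: ConeCatch) -> float:
    """Double-cone catch: the achromatic signal of the modelled viewer."""
    if catch.q_DBL is None:
        raise ValueError("luminance requires a double-cone catch")
    return float(catch.q_DBL)


def pattern_area(polygon: np.ndarray, scale: float) -> float:
    """Area in cm^2 of a simple polygon given ``scale`` pixels per cm.

    Uses the shoelace formula; vertex order does not matter.  Raises on
    self-intersecting polygons.
    """
    if scale <= 0:
        raise ValueError("scale must be positive (pixels per cm)")
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("polygon must be an (n>=3, 2) vertex array")
    if not _ShapelyPolygon(pts).is_valid:
        raise ValueError("polygon is self-intersecting or degenerate")
    x, y = pts[:, 0], pts[:, 1]
    area_px = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(area_px / scale**2)
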