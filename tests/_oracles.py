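"""Independent brute-force geometric oracles used only by the tests.

Built on shapely so they share no code path with the package's vectorised
numpy implementations.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import LineString, Point

from goldstereo.stereology import GridSpec


def brute_force_crossings(points: np.ndarray, grid: GridSpec) -> int:
    """Count (segment, lattice line) crossings by testing every pair.

    Enumerates every lattice line overlapping the polyline's bounding box
    (in the grid frame) and intersects it with every segment via shapely.
    Point/MultiPoint intersections count; collinear overlap counts zero.
    """
    pts = np.asarray(points, dtype=float)
    ca, sa = math.cos(grid.angle_rad), math.sin(grid.angle_rad)
    # grid frame coordinates of the polyline
    gx = pts[:, 0] * ca + pts[:, 1] * sa
    gy = -pts[:, 0] * sa + pts[:, 1] * ca
    d = grid.spacing_nm
    dx, dy = grid.offset
    pad = 2.0 * d

    lines = []
    # family perpendicular to the grid-frame x axis: x = dx + k*d
    for k in range(
        math.floor((gx.min() - pad - dx) / d), math.ceil((gx.max() + pad - dx) / d) + 1
    ):
        x = dx + k * d
        a = _to_world(x, gy.min() - pad, ca, sa)
        b = _to_world(x, gy.max() + pad, ca, sa)
        lines.append(LineString([a, b]))
    # family perpendicular to the grid-frame y axis: y = dy + k*d
    for k in range(
        math.floor((gy.min() - pad - dy) / d), math.ceil((gy.max() + pad - dy) / d) + 1
    ):
        y = dy + k * d
        a = _to_world(gx.min() - pad, y, ca, sa)
        b = _to_world(gx.max() + pad, y, ca, sa)
        lines.append(LineString([a, b]))

    total = 0
    for p, q in zip(pts[:-1], pts[1:]):
        seg = LineString([p, q])
        for line in lines:
            inter = seg.intersection(line)
            if inter.is_empty:
                continue
            if inter.geom_type == "Point":
                total += 1
            elif inter.geom_type == "MultiPoint":
                total += len(inter.geoms)
            # LineString overlap = collinear segment: contributes zero
    return total


def _to_world(x: float, y: float, ca: float, sa: float) -> tuple[float, float]:
    return (x * ca - y * sa, x * sa + y * ca)


def brute_force_distance(point, polyline: np.ndarray) -> float:
    """Min distance to a polyline by per-segment shapely minimisation."""
    pts = np.asarray(polyline, dtype=float)
    p = Point(point)
    return min(
        LineString([a, b]).distance(p) for a, b in zip(pts[:-1], pts[1:])
    )
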