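"""Polygon regions for nuclei, compartments and nucleoli.

All coordinates are micrometres, 2-D, origin at the image top-left with y
increasing downward.  Containment is edge-inclusive: a point exactly on a
polygon edge counts as inside.  This tie-break is applied consistently by
every analysis in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon


class GeometryError(ValueError):
    """Invalid region geometry (self-intersection, degenerate area ...)."""


@dataclass(frozen=True)
class PolygonRegion:
    """A closed simple polygon given by its ordered vertices (µm).

    Parameters
    ----------
    vertices : (n, 2) array-like
        Ordered (x, y) vertex pairs; the closing edge is implicit.
    """

    vertices: np.ndarray
    _poly: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise GeometryError("polygon needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(verts)):
            raise GeometryError("polygon vertices must be finite")
        object.__setattr__(self, "vertices", verts)
        poly = Polygon(verts)
        if not poly.is_valid:
            raise GeometryError("polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise GeometryError("polygon has non-positive area")
        object.__setattr__(self, "_poly", poly)

    @property
    def shapely(self) -> Polygon:
        return self._poly

    @property
    def area(self) -> float:
        return self._poly.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return self._poly.bounds

    def contains(self, x, y) -> np.ndarray:
        """Edge-inclusive containment test, vectorized over points."""
        pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return shapely.covers(self._poly, pts)

    def contains_point(self, x: float, y: float) -> bool:
        return bool(self._poly.covers(Point(x, y)))

    def boundary_distance(self, x, y) -> np.ndarray:
        """Distance from each point to the polygon boundary (µm)."""
        pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return shapely.distance(self._poly.exterior, pts)

    def translated(self, dx: float, dy: float) -> "PolygonRegion":
        return PolygonRegion(self.vertices + np.array([dx, dy]))

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Rejection-sample ``n`` points uniformly inside the region."""
        xmin, ymin, xmax, ymax = self.bounds
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            m = max(4 * (n - filled), 16)
            x = rng.uniform(xmin, xmax, m)
            y = rng.uniform(ymin, ymax, m)
            ok = self.contains(x, y)
            k = min(int(ok.sum()), n - filled)
            sel = np.flatnonzero(ok)[:k]
            out[filled : filled + k, 0] = x[sel]
            out[filled : filled + k, 1] = y[sel]
            filled += k
        return out


def square(side: float, x0: float = 0.0, y0: float = 0.0) -> PolygonRegion:
    """Axis-aligned square region of the given side length (µm)."""
    return PolygonRegion(
        [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]
    )


def regular_polygon(
    n: int, radius: float, cx: float = 0.0, cy: float = 0.0
) -> PolygonRegion:
    """Regular n-gon; with large n a good stand-in for a disc (e.g. a nucleus)."""
    ang = 2 * np.pi * np.arange(n) / n
    return PolygonRegion(
        np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)])
    )
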