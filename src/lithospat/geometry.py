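"""Planar windows, marked point patterns and nearest-neighbour primitives.

All coordinates are planar metres in a local site grid; there is no CRS
handling.  Analysis is strictly two-dimensional -- elevations, if present,
travel as ordinary mark columns and are never used in distance computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon


class ValidationError(ValueError):
    """A point pattern or window failed a structural invariant."""


class SchemaError(ValueError):
    """Tabular input does not match the documented schema."""


@dataclass(frozen=True)
class Window:
    """A simple polygonal observation window.

    Parameters
    ----------
    vertices
        Ordered exterior ring, ``(x, y)`` in metres.  The ring may be given
        open or closed; it is stored open.  The polygon must be simple
        (non-self-intersecting) with strictly positive area.
    """

    vertices: tuple = ()
    _polygon: Polygon = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        verts = [tuple(map(float, v)) for v in self.vertices]
        if len(verts) >= 2 and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValidationError("window needs at least 3 vertices")
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ValidationError("window polygon is not simple (self-intersecting or degenerate)")
        if poly.area <= 0:
            raise ValidationError("window polygon has zero area")
        object.__setattr__(self, "vertices", tuple(verts))
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area_m2(self) -> float:
        return float(self._polygon.area)

    @property
    def bounds(self) -> tuple:
        """(xmin, ymin, xmax, ymax)."""
        return tuple(self._polygon.bounds)

    @property
    def diameter(self) -> float:
        """Largest inter-vertex distance (the polygon diameter)."""
        v = np.asarray(self.vertices, float)
        d = np.sqrt(((v[:, None, :] - v[None, :, :]) ** 2).sum(-1))
        return float(d.max())

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Closed containment test: boundary points count as inside."""
        coords = np.atleast_2d(np.asarray(coords, float))
        pts = shapely.points(coords)
        return shapely.covers(self._polygon, pts)

    def boundary_distance(self, coords: np.ndarray) -> np.ndarray:
        """Distance from each point to the window boundary."""
        coords = np.atleast_2d(np.asarray(coords, float))
        pts = shapely.points(coords)
        return shapely.distance(self._polygon.exterior, pts)

    @classmethod
    def from_wkt(cls, wkt: str) -> "Window":
        geom = shapely.from_wkt(wkt)
        if geom.geom_type != "Polygon":
            raise ValidationError(f"expected POLYGON WKT, got {geom.geom_type}")
        return cls(tuple(geom.exterior.coords))

    def to_wkt(self) -> str:
        return self._polygon.wkt

    @classmethod
    def rectangle(cls, xmin: float, ymin: float, xmax: float, ymax: float) -> "Window":
        return cls(((xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)))

    @classmethod
    def unit_square(cls) -> "Window":
        return cls.rectangle(0.0, 0.0, 1.0, 1.0)


@dataclass(frozen=True)
class PointPattern:
    """Planar marked point pattern inside a :class:`Window`.

    ``coords`` is an ``(n, 2)`` float array; ``marks`` is a DataFrame with
    one row per point (possibly zero columns).  Construct through
    :func:`build_pattern`, which validates containment and mark lengths.
    """

    coords: np.ndarray
    window: Window
    marks: pd.DataFrame

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def mark(self, name: str) -> np.ndarray:
        return self.marks[name].to_numpy()

    def subset(self, index) -> "PointPattern":
        index = np.asarray(index)
        return PointPattern(
            self.coords[index],
            self.window,
            self.marks.iloc[index].reset_index(drop=True),
        )

    def with_marks(self, marks: Mapping[str, Sequence]) -> "PointPattern":
        new = self.marks.copy()
        for name, col in marks.items():
            col = np.asarray(col)
            if len(col) != self.n:
                raise SchemaError(
                    f"mark column {name!r} has length {len(col)}, expected {self.n}"
                )
            new[name] = col
        return PointPattern(self.coords, self.window, new)

    def split_by(self, mark_name: str) -> dict:
        """Sub-patterns by the levels of a categorical mark."""
        values = self.mark(mark_name)
        return {
            level: self.subset(np.flatnonzero(values == level))
            for level in pd.unique(values)
        }


def build_pattern(
    coords: Iterable,
    window: Window,
    marks: Mapping[str, Sequence] | pd.DataFrame | None = None,
) -> PointPattern:
    """Validate coordinates and marks and assemble a :class:`PointPattern`.

    Points must lie inside or on the boundary of ``window`` (closed
    containment); every mark column must have exactly ``n`` entries.
    Duplicate coordinates are permitted -- two artifacts can legitimately be
    plotted at the same total-station reading.
    """
    coords = np.asarray(coords, float)
    if coords.size == 0:
        coords = coords.reshape(0, 2)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValidationError(f"coords must be (n, 2), got shape {coords.shape}")
    if not np.all(np.isfinite(coords)):
        bad = np.flatnonzero(~np.isfinite(coords).all(axis=1))
        raise ValidationError(f"non-finite coordinates at rows {bad.tolist()[:10]}")
    n = coords.shape[0]

    if n > 0:
        inside = window.contains(coords)
        if not inside.all():
            bad = np.flatnonzero(~inside)
            raise ValidationError(
                f"{bad.size} point(s) outside the window, first offending rows: "
                f"{bad.tolist()[:10]}"
            )

    if marks is None:
        marks_df = pd.DataFrame(index=pd.RangeIndex(n))
    elif isinstance(marks, pd.DataFrame):
        if len(marks) != n:
            raise SchemaError(f"marks have {len(marks)} rows, expected {n}")
        marks_df = marks.reset_index(drop=True)
    else:
        marks_df = pd.DataFrame(index=pd.RangeIndex(n))
        for name, col in marks.items():
            col = np.asarray(col)
            if len(col) != n:
                raise SchemaError(
                    f"mark column {name!r} has length {len(col)}, expected {n}"
                )
            marks_df[name] = col
    return PointPattern(coords, window, marks_df)


@dataclass(frozen=True)
class DistanceStructure:
    """Ordered nearest neighbours of every point up to order ``k_max``.

    ``indices[i, k-1]`` and ``distances[i, k-1]`` give point *i*'s k-th
    nearest neighbour.  A point is never its own neighbour; distance ties are
    broken by lowest point index so Monte-Carlo reruns are reproducible.
    """

    indices: np.ndarray
    distances: np.ndarray

    @property
    def k_max(self) -> int:
        return self.indices.shape[1]

    def nn_dist(self, k: int = 1) -> np.ndarray:
        """k-th nearest-neighbour distances for all points."""
        return self.distances[:, k - 1]


def nn_distances(pp: PointPattern, k_max: int = 1) -> DistanceStructure:
    """Exact Euclidean k-nearest-neighbour structure of a pattern.

    Requires ``n >= k_max + 1``.  Duplicate coordinates yield zero
    distances with the duplicate as the neighbour.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n = pp.n
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be smaller than n={n}")
    tree = cKDTree(pp.coords)
    # query one extra so the self entry can be removed even under ties
    d, idx = tree.query(pp.coords, k=k_max + 1)
    rows = np.arange(n)
    out_idx = np.empty((n, k_max), dtype=np.int64)
    out_d = np.empty((n, k_max), dtype=float)
    for i in rows:
        ii, dd = idx[i], d[i]
        keep = ii != i
        if keep.sum() == k_max + 1:  # self not returned (duplicate ties)
            keep[-1] = False
        ii, dd = ii[keep][:k_max], dd[keep][:k_max]
        # deterministic tie rule: among equal distances, lowest index first
        order = np.lexsort((ii, dd))
        out_idx[i], out_d[i] = ii[order], dd[order]
    return DistanceStructure(out_idx, out_d)
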