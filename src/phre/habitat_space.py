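"""Transforms between geographic coordinates and habitat-defined landscape space.

The landscape coordinate system replaces planar (x, y) with axes that track the
habitat features an animal actually navigates by: a decimal *coastal position*
along an indexed reference polyline (the "as the otter swims" axis), the natural
log of distance from shore, and optionally further habitat-layer values such as
depth.  Working in these coordinates straightens out a tortuous coastline and,
crucially, makes land unreachable: a point on land has distance-from-shore <= 0
and no landscape image, so it can never receive probability mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString, MultiPolygon, Polygon
from shapely.ops import unary_union

__all__ = [
    "ReferenceLine",
    "LandPolygons",
    "LandscapeCoordinates",
    "coastal_position",
    "distance_to_shore",
    "to_landscape",
    "read_reference_line",
    "read_habitat_table",
]


@dataclass(frozen=True)
class ReferenceLine:
    """An ordered, sequentially indexed polyline along a habitat axis.

    Vertices are planar points in meters; ``indices`` are consecutive integer
    labels (e.g. the ATOS point numbers).  ``spacing`` is the nominal
    inter-vertex distance in meters and is informational only — all geometry
    uses the actual vertex positions.
    """

    vertices: np.ndarray  # (n, 2) float
    start_index: int = 0
    spacing: float = 500.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("reference line needs >= 2 planar vertices")
        if not np.isfinite(v).all():
            raise ValueError("reference line vertices must be finite")
        if (np.linalg.norm(np.diff(v, axis=0), axis=1) == 0).any():
            raise ValueError("consecutive reference-line vertices must be distinct")
        object.__setattr__(self, "vertices", v)

    @property
    def indices(self) -> np.ndarray:
        return self.start_index + np.arange(len(self.vertices))

    @property
    def index_range(self) -> tuple[int, int]:
        return self.start_index, self.start_index + len(self.vertices) - 1

    def as_linestring(self) -> LineString:
        return LineString(self.vertices)

    def point_at(self, position: float | np.ndarray) -> np.ndarray:
        """Geographic point(s) at decimal index position(s), by linear interpolation."""
        pos = np.atleast_1d(np.asarray(position, dtype=float)) - self.start_index
        n_seg = len(self.vertices) - 1
        if (pos < 0).any() or (pos > n_seg).any():
            raise ValueError("position outside the reference line's index range")
        i = np.clip(pos.astype(int), 0, n_seg - 1)
        f = pos - i
        p = self.vertices[i] + f[:, None] * (self.vertices[i + 1] - self.vertices[i])
        return p if np.ndim(position) else p[0]

    def segment_normal(self, position: float | np.ndarray) -> np.ndarray:
        """Unit normal(s) of the segment under each decimal position (left of travel)."""
        pos = np.atleast_1d(np.asarray(position, dtype=float)) - self.start_index
        i = np.clip(pos.astype(int), 0, len(self.vertices) - 2)
        d = self.vertices[i + 1] - self.vertices[i]
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        n = np.column_stack([-d[:, 1], d[:, 0]])
        return n if np.ndim(position) else n[0]


@dataclass(frozen=True)
class LandPolygons:
    """Land as a union of planar polygons; point-in-polygon means 'on land'."""

    geometry: Polygon | MultiPolygon

    def __post_init__(self) -> None:
        geom = self.geometry
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
        geom = unary_union(geom)
        if geom.is_empty:
            raise ValueError("land layer is empty")
        object.__setattr__(self, "geometry", geom)

    @classmethod
    def from_wkt(cls, wkt: str) -> "LandPolygons":
        return cls(shapely.from_wkt(wkt))

    @classmethod
    def from_geojson(cls, text: str) -> "LandPolygons":
        import json

        obj = json.loads(text)
        if obj.get("type") == "FeatureCollection":
            geoms = [shapely.geometry.shape(f["geometry"]) for f in obj["features"]]
            return cls(unary_union(geoms))
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        return cls(shapely.geometry.shape(obj))

    @property
    def boundary(self):
        return self.geometry.boundary


@dataclass(frozen=True)
class LandscapeCoordinates:
    """A sighting's position in landscape space."""

    coastal_position: float
    dist_shore: float
    log_dist: float
    extra_axes: tuple[float, ...] = field(default_factory=tuple)

    def as_array(self) -> np.ndarray:
        return np.array([self.coastal_position, self.log_dist, *self.extra_axes])


def _project_on_segments(points: np.ndarray, line: ReferenceLine):
    """Project points onto every segment; return (frac_position, sq_distance).

    ``frac_position`` is (n_pts,) decimal index units; ties between segments go
    to the lower-indexed segment (argmin keeps the first minimum).
    """
    a = line.vertices[:-1]  # (s, 2)
    b = line.vertices[1:]
    ab = b - a
    len2 = (ab**2).sum(axis=1)  # segments are non-degenerate by invariant
    ap = points[:, None, :] - a[None, :, :]  # (n, s, 2)
    t = np.clip((ap * ab[None]).sum(axis=2) / len2[None], 0.0, 1.0)  # (n, s)
    proj = a[None] + t[..., None] * ab[None]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    seg = d2.argmin(axis=1)
    rows = np.arange(len(points))
    return line.start_index + seg + t[rows, seg], d2[rows, seg]


def coastal_position(
    points: np.ndarray | Sequence[float], line: ReferenceLine
) -> np.ndarray | float:
    """Decimal coastal position of point(s) along an indexed reference line.

    The point is perpendicularly projected onto each line segment; the nearest
    projection wins and the result is ``segment_index + fraction`` — e.g. a
    point projecting one third of the way between line points 367 and 368 gets
    coastal position 367.33.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    pos, _ = _project_on_segments(pts, line)
    return pos if np.asarray(points).ndim == 2 else float(pos[0])


def distance_to_shore(
    points: np.ndarray | Sequence[float], land: LandPolygons
) -> np.ndarray | float:
    """Signed distance (m) to the nearest shoreline: > 0 in water, < 0 on land.

    Every point is classified: water points return the positive Euclidean
    distance to the land boundary, boundary points return 0, and points inside
    land return minus their distance to the boundary so that callers can detect
    impermissible locations.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    d = shapely.distance(geoms, land.boundary)
    inside = shapely.contains_xy(land.geometry, pts[:, 0], pts[:, 1])
    d = np.where(inside, -d, d)
    return d if np.asarray(points).ndim == 2 else float(d[0])


class HabitatLayers:
    """Gridded habitat layers sampled by nearest grid point (S-file table schema)."""

    def __init__(self, xy: np.ndarray, values: np.ndarray, names: Sequence[str],
                 max_snap: float | None = None):
        self.xy = np.asarray(xy, dtype=float)
        self.values = np.atleast_2d(np.asarray(values, dtype=float))
        if self.values.shape[0] != self.xy.shape[0]:
            self.values = self.values.T
        self.names = list(names)
        self._tree = cKDTree(self.xy)
        # points farther than this from any grid node are 'outside the grid'
        if max_snap is None:
            d, _ = self._tree.query(self.xy[: min(len(self.xy), 256)], k=2)
            max_snap = 2.0 * float(np.median(d[:, 1]))
        self.max_snap = max_snap

    def sample(self, points: np.ndarray) -> np.ndarray:
        d, idx = self._tree.query(np.atleast_2d(points))
        if (d > self.max_snap).any():
            bad = int(np.argmax(d > self.max_snap))
            raise ValueError(
                f"point {bad} falls outside the habitat grid "
                f"(nearest node {d[bad]:.0f} m away, limit {self.max_snap:.0f} m)"
            )
        return self.values[idx]


def to_landscape(
    points: np.ndarray,
    line: ReferenceLine,
    land: LandPolygons,
    layers: HabitatLayers | None = None,
) -> list[LandscapeCoordinates]:
    """Map geographic points to landscape coordinates.

    Each point becomes (coastal_position, ln distance-from-shore [, habitat
    layer values]).  Points on or inside land are rejected with an error naming
    the offending record: the method's premise is that every sighting is in
    water, and ln(d) is undefined at d <= 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.asarray(distance_to_shore(pts, land))
    if (d <= 0).any():
        bad = int(np.argmax(d <= 0))
        raise ValueError(
            f"sighting {bad} at ({pts[bad, 0]:.1f}, {pts[bad, 1]:.1f}) is on land "
            f"(distance to shore {d[bad]:.1f} m); all sightings must be in water"
        )
    cp = np.asarray(coastal_position(pts, line))
    extras = layers.sample(pts) if layers is not None else None
    out = []
    for i in range(len(pts)):
        ex = tuple(extras[i]) if extras is not None else ()
        out.append(LandscapeCoordinates(float(cp[i]), float(d[i]), float(np.log(d[i])), ex))
    return out


def landscape_array(coords: Sequence[LandscapeCoordinates]) -> np.ndarray:
    """Stack landscape coordinates into an (n, d) array [cp, log_dist, extras...]."""
    return np.array([c.as_array() for c in coords])


# ---------------------------------------------------------------------------
# readers


def read_reference_line(path) -> ReferenceLine:
    """Read a reference line from a CSV of (index, x, y)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        idx, x, y = (df[cols[k]].to_numpy() for k in ("index", "x", "y"))
    except KeyError as e:
        raise ValueError(f"reference line CSV missing column {e}") from None
    order = np.argsort(idx)
    idx, x, y = idx[order], x[order], y[order]
    if not np.array_equal(np.diff(idx), np.ones(len(idx) - 1)):
        raise ValueError("reference line indices must increase by exactly 1")
    gaps = np.linalg.norm(np.diff(np.column_stack([x, y]), axis=0), axis=1)
    return ReferenceLine(np.column_stack([x, y]), int(idx[0]), float(np.median(gaps)))


_HABITAT_ALIASES = {
    "x": ("x", "tealex"),
    "y": ("y", "tealey"),
    "coastal_position": ("coastal_position", "atoscal", "atos"),
    "distance_m": ("distance_m", "distance", "dist"),
    "depth_m": ("depth_m", "depth"),
}


def read_habitat_table(path) -> pd.DataFrame:
    """Read a habitat point table (x, y, coastal_position, distance_m[, depth_m]).

    Tolerates the original column spellings (TealeX, TealeY, ATOScal, Distance,
    depth) and extra columns, which are preserved.
    """
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for canon, aliases in _HABITAT_ALIASES.items():
        for a in aliases:
            if a in lower:
                rename[lower[a]] = canon
                break
    df = df.rename(columns=rename)
    missing = {"x", "y", "coastal_position", "distance_m"} - set(df.columns)
    if missing:
        raise ValueError(f"habitat table missing columns: {sorted(missing)}")
    return df
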