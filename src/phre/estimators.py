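"""Home-range estimators behind a common contract.

The evaluation harness compares estimators through a minimal contract: fit to
sightings + habitat, expose a normalized probability grid, and derive isopleth
home ranges from that grid.  Because every estimator shares the same isopleth
and polygonization machinery, differences between methods are attributable to
their density surfaces alone.

Provided estimators:

* :class:`PHREEstimator` — the landscape-space method (transform, adaptive KDE,
  back-transform with land exclusion).
* :class:`GeographicKDE` — the conventional planar KDE comparator, with the
  same adaptive bandwidth rule applied in meters and *no* land masking, so it
  may spill probability onto land exactly as a symmetric kernel must.
* :func:`import_external_homerange` — wraps a third-party probability grid or
  isopleth-polygon stack (e.g. from a local-convex-hull package) so external
  methods can join the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Protocol

import numpy as np
import shapely

from . import home_range as hr_mod
from . import landscape_kde as kde_mod
from .habitat_space import HabitatLayers, LandPolygons, ReferenceLine, to_landscape
from .home_range import HomeRange, ProbabilityGrid, build_grid

__all__ = [
    "Estimator",
    "PHREEstimator",
    "GeographicKDE",
    "FixedGridEstimator",
    "import_external_homerange",
]


class Estimator(Protocol):
    """Contract every comparable home-range estimator fulfils."""

    def fit(self, sightings: np.ndarray) -> "Estimator": ...

    def probability_grid(self) -> ProbabilityGrid: ...

    def home_range(self, level: float = 0.90) -> HomeRange: ...


@dataclass
class PHREEstimator:
    """Permissible home range estimation: KDE in landscape space, land excluded."""

    line: ReferenceLine
    land: LandPolygons
    layers: HabitatLayers | None = None
    use_layers: bool = False  # True adds layer axes (e.g. depth) to the fit
    spec: kde_mod.BandwidthSpec = kde_mod.BandwidthSpec()
    cell_size: float = 100.0
    pad: float = 5000.0
    isopleth_level: float = 0.90

    def fit(self, sightings: np.ndarray) -> "PHREEstimator":
        self.sightings_ = np.atleast_2d(np.asarray(sightings, dtype=float))
        layers = self.layers if self.use_layers else None
        coords = to_landscape(self.sightings_, self.line, self.land, layers)
        self.model_ = kde_mod.fit(coords, self.spec)
        self._grid = None
        return self

    def probability_grid(self) -> ProbabilityGrid:
        if getattr(self, "_grid", None) is None:
            empty = build_grid(self.sightings_, self.land, self.cell_size, self.pad)
            self._grid = hr_mod.backtransform(
                self.model_, empty, self.line, self.land,
                layers=self.layers if self.use_layers else None,
            )
        return self._grid

    def home_range(self, level: float | None = None) -> HomeRange:
        level = self.isopleth_level if level is None else level
        return hr_mod.home_range(self.probability_grid(), level, self.line)


@dataclass
class GeographicKDE:
    """Planar Gaussian KDE on (x, y) with the adaptive bandwidth rule in meters.

    The baseline smoothing parameter is 30,000 (meters, the unit the axes
    carry), adapted per animal with the same h = h_b * (d/4) ** 2.5 rule where
    d is the mean nearest-neighbor distance between sightings in the plane.
    The same bandwidth is used isotropically on both axes, and no land mask is
    applied: the estimator is free to place probability on land.
    """

    land: LandPolygons | None = None  # only for the grid's land_mask bookkeeping
    h_b: float = 30_000.0
    divisor: float = 4.0
    exponent: float = 2.5
    h_floor: float = 1.0  # meters
    cell_size: float = 100.0
    pad: float = 5000.0
    isopleth_level: float = 0.90

    def fit(self, sightings: np.ndarray) -> "GeographicKDE":
        pts = np.atleast_2d(np.asarray(sightings, dtype=float))
        if len(pts) < 2:
            raise ValueError("geographic KDE needs >= 2 sightings")
        self.sightings_ = pts
        d_geo = self._mean_nn_distance_2d(pts)
        h = max(self.h_floor, self.h_b * (d_geo / self.divisor) ** self.exponent)
        self.d_geo_ = d_geo
        self.h_ = h
        self.model_ = kde_mod.KernelDensityModel(pts, np.array([h, h]))
        self._grid = None
        return self

    @staticmethod
    def _mean_nn_distance_2d(pts: np.ndarray) -> float:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(pts, k=2)
        return float(d[:, 1].mean())

    def probability_grid(self) -> ProbabilityGrid:
        if getattr(self, "_grid", None) is None:
            grid = build_grid(self.sightings_, self.land, self.cell_size, self.pad)
            dens = self.model_.evaluate(grid.cell_centers())
            total = dens.sum()
            if total <= 0:
                raise ValueError("degenerate geographic KDE (zero mass on grid)")
            grid.prob = (dens / total).reshape(grid.ny, grid.nx)
            grid.normalized = True
            self._grid = grid
        return self._grid

    def home_range(self, level: float | None = None) -> HomeRange:
        level = self.isopleth_level if level is None else level
        return hr_mod.home_range(self.probability_grid(), level)


@dataclass
class FixedGridEstimator:
    """Wraps a precomputed probability grid (an imported external estimate)."""

    grid: ProbabilityGrid

    def fit(self, sightings: np.ndarray) -> "FixedGridEstimator":
        return self

    def probability_grid(self) -> ProbabilityGrid:
        return self.grid

    def home_range(self, level: float = 0.90) -> HomeRange:
        return hr_mod.home_range(self.grid, level)


def _rasterize_isopleth_stack(
    polygons: list[tuple[float, shapely.Geometry]],
    cell_size: float = 100.0,
    pad: float = 1000.0,
) -> ProbabilityGrid:
    """Probability surface from a nested stack of isopleth polygons.

    Each cell is scored by the innermost (smallest-level) isopleth containing
    its center; scores are then rescaled to sum to 1.  Any strictly monotone
    level-to-score map yields the same ROC ranking, so the particular values
    are immaterial for threshold-free evaluation.
    """
    stack = sorted(polygons, key=lambda lv: lv[0])
    for (l1, g1), (l2, g2) in zip(stack, stack[1:]):
        if not g2.buffer(1e-6).contains(g1):
            raise ValueError(f"isopleths not nested: {l1}% not within {l2}%")
    outer = stack[-1][1]
    x0, y0, x1, y1 = outer.bounds
    nx = int(np.floor((x1 - x0 + 2 * pad) / cell_size)) + 1
    ny = int(np.floor((y1 - y0 + 2 * pad) / cell_size)) + 1
    grid = ProbabilityGrid(
        (x0 - pad, y0 - pad), cell_size, np.zeros((ny, nx)),
        np.zeros((ny, nx), dtype=bool),
    )
    c = grid.cell_centers()
    score = np.zeros(len(c))
    # innermost containing isopleth wins: iterate outside-in, overwrite inward
    for level, geom in sorted(stack, key=lambda lv: -lv[0]):
        inside = shapely.intersects_xy(geom, c[:, 0], c[:, 1])
        score[inside] = 110.0 - level  # any decreasing map of level works
    total = score.sum()
    if total <= 0:
        raise ValueError("isopleth stack covers no grid cells")
    grid.prob = (score / total).reshape(ny, nx)
    grid.normalized = True
    return grid


def import_external_homerange(path, cell_size: float = 100.0) -> FixedGridEstimator:
    """Load a third-party estimate: an ASCII/CSV probability grid or a GeoJSON
    isopleth stack (features carrying a 'level' property in percent)."""
    import json
    from pathlib import Path

    from . import gridio

    p = Path(path)
    if p.suffix.lower() in {".asc", ".agr"}:
        return FixedGridEstimator(gridio.read_ascii_grid(p))
    if p.suffix.lower() == ".csv":
        return FixedGridEstimator(gridio.read_grid_csv(p))
    if p.suffix.lower() in {".geojson", ".json"}:
        obj = json.loads(p.read_text())
        feats = obj["features"] if obj.get("type") == "FeatureCollection" else [obj]
        stack = []
        for f in feats:
            level = float(f.get("properties", {}).get("level"))
            stack.append((level, shapely.geometry.shape(f["geometry"])))
        if not stack:
            raise ValueError("no isopleth features found")
        return FixedGridEstimator(_rasterize_isopleth_stack(stack, cell_size))
    raise ValueError(f"unrecognized home-range file type: {p.suffix}")
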