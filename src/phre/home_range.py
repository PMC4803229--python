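"""Geographic probability grids, land masking, isopleths, and home-range polygons.

The fitted landscape-space density is *back-transformed* by evaluating it at the
landscape image of every water cell center of a regular geographic grid.  Land
cells are assigned exactly zero, and the grid is normalized so cell values sum
to one — a discrete utilization distribution in which impermissible habitat
carries no probability by construction.  The home range at a level (default
90%) is the smallest set of cells whose cumulative probability reaches that
level; its cells are dissolved into polygons, so polygon area is an exact cell
count and the zero-on-land property survives polygonization exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import box
from shapely.ops import unary_union

from .habitat_space import LandPolygons, ReferenceLine, coastal_position, distance_to_shore
from .landscape_kde import KernelDensityModel

__all__ = [
    "ProbabilityGrid",
    "HomeRange",
    "build_grid",
    "backtransform",
    "isopleth_cells",
    "polygonize",
    "home_range",
    "length_along_line",
]


@dataclass
class ProbabilityGrid:
    """A regular geographic grid of cell probabilities.

    ``origin`` is the (x, y) of the *center* of cell (0, 0); cells are squares
    of side ``cell_size`` meters.  ``prob`` has shape (ny, nx) with row 0 at
    the bottom (south).  After normalization the probabilities sum to 1 and are
    exactly 0 wherever ``land_mask`` is true.
    """

    origin: tuple[float, float]
    cell_size: float
    prob: np.ndarray  # (ny, nx)
    land_mask: np.ndarray  # (ny, nx) bool
    normalized: bool = False

    @property
    def nx(self) -> int:
        return self.prob.shape[1]

    @property
    def ny(self) -> int:
        return self.prob.shape[0]

    def cell_centers(self) -> np.ndarray:
        """(ny*nx, 2) array of cell-center coordinates, row-major from the south."""
        x = self.origin[0] + self.cell_size * np.arange(self.nx)
        y = self.origin[1] + self.cell_size * np.arange(self.ny)
        xx, yy = np.meshgrid(x, y)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def lookup(self, points: np.ndarray) -> np.ndarray:
        """Probability of the cell containing each point; 0 for off-grid points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ix = np.round((pts[:, 0] - self.origin[0]) / self.cell_size).astype(int)
        iy = np.round((pts[:, 1] - self.origin[1]) / self.cell_size).astype(int)
        ok = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        out = np.zeros(len(pts))
        out[ok] = self.prob[iy[ok], ix[ok]]
        return out

    def cell_polygon(self, iy: int, ix: int):
        cx = self.origin[0] + ix * self.cell_size
        cy = self.origin[1] + iy * self.cell_size
        h = self.cell_size / 2
        return box(cx - h, cy - h, cx + h, cy + h)


@dataclass
class HomeRange:
    """Isopleth polygons at a probability level, with area and along-line length."""

    polygons: shapely.Geometry
    level: float
    area_km2: float
    contained_mass: float
    length_km: float | None = None
    cells: np.ndarray | None = field(default=None, repr=False)  # (k, 2) (iy, ix)


def build_grid(
    sightings: np.ndarray,
    land: LandPolygons | None,
    cell_size: float = 100.0,
    pad: float = 5000.0,
) -> ProbabilityGrid:
    """Empty probability grid covering the sightings' bounding box plus a pad.

    The land mask is set from the cell centers: a cell is land when its center
    lies on or inside the land union.
    """
    pts = np.atleast_2d(np.asarray(sightings, dtype=float))
    if pts.size == 0:
        raise ValueError("cannot build a grid around zero sightings")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    nx = int(np.floor((x1 - x0) / cell_size)) + 1
    ny = int(np.floor((y1 - y0) / cell_size)) + 1
    grid = ProbabilityGrid(
        origin=(float(x0), float(y0)),
        cell_size=float(cell_size),
        prob=np.zeros((ny, nx)),
        land_mask=np.zeros((ny, nx), dtype=bool),
    )
    if land is not None:
        c = grid.cell_centers()
        on_land = shapely.intersects_xy(land.geometry, c[:, 0], c[:, 1])
        grid.land_mask = on_land.reshape(ny, nx)
    return grid


def backtransform(
    model: KernelDensityModel,
    grid: ProbabilityGrid,
    line: ReferenceLine,
    land: LandPolygons,
    layers=None,
    edge_mass_warn: float = 1e-3,
) -> ProbabilityGrid:
    """Evaluate the landscape density at water cell centers and normalize.

    Each water cell center is mapped to landscape coordinates and assigned the
    model density there; land cells get 0.  Values are then divided by their
    sum so the grid is a probability distribution.  A warning is emitted when
    more than ``edge_mass_warn`` of the unnormalized mass sits in the outermost
    cell ring, a sign the grid truncates the density's support.
    """
    centers = grid.cell_centers()
    water = ~grid.land_mask.ravel()
    wc = centers[water]
    dens = np.zeros(centers.shape[0])
    if water.any():
        d = np.asarray(distance_to_shore(wc, land))
        # centers can sit in water cells yet on the land side numerically; only
        # strictly-positive distances have a landscape image
        ok = d > 0
        q = np.empty((ok.sum(), model.n_dims))
        q[:, 0] = np.asarray(coastal_position(wc[ok], line))
        q[:, 1] = np.log(d[ok])
        if model.n_dims > 2:
            if layers is None:
                raise ValueError("model has extra axes but no habitat layers given")
            q[:, 2:] = layers.sample(wc[ok])
        vals = np.zeros(len(wc))
        vals[ok] = model.evaluate(q)
        dens[water] = vals
    total = dens.sum()
    if total <= 0:
        raise ValueError("grid carries no probability mass (all land?)")
    dens2 = dens.reshape(grid.ny, grid.nx)
    edge = dens2.sum() - dens2[1:-1, 1:-1].sum()
    if edge / total > edge_mass_warn:
        warnings.warn(
            f"{100 * edge / total:.2f}% of unnormalized mass lies in the outermost "
            "cell ring; enlarge the grid pad to avoid truncation bias",
            stacklevel=2,
        )
    out = ProbabilityGrid(grid.origin, grid.cell_size, dens2 / total,
                          grid.land_mask.copy(), normalized=True)
    return out


def isopleth_cells(grid: ProbabilityGrid, level: float = 0.90) -> np.ndarray:
    """Cells of the smallest set whose cumulative probability reaches ``level``.

    Cells are taken in order of decreasing probability until the cumulative sum
    reaches the level; cells tied with the last-included probability value are
    all included, making the result order-independent.  Returns (k, 2) integer
    (iy, ix) pairs.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    p = grid.prob.ravel()
    order = np.argsort(p)[::-1]
    csum = np.cumsum(p[order])
    k = int(np.searchsorted(csum, level * (1 - 1e-12))) + 1
    k = min(k, len(order))
    thresh = p[order[k - 1]]
    chosen = np.flatnonzero(p >= thresh) if thresh > 0 else order[:k]
    iy, ix = np.unravel_index(chosen, grid.prob.shape)
    return np.column_stack([iy, ix])


def polygonize(cells: np.ndarray, grid: ProbabilityGrid) -> shapely.Geometry:
    """Dissolve the selected cells' square footprints into maximal polygons."""
    cells = np.atleast_2d(np.asarray(cells, dtype=int))
    if cells.size == 0:
        raise ValueError("no cells to polygonize")
    h = grid.cell_size / 2.0
    cx = grid.origin[0] + cells[:, 1] * grid.cell_size
    cy = grid.origin[1] + cells[:, 0] * grid.cell_size
    boxes = shapely.box(cx - h, cy - h, cx + h, cy + h)
    return shapely.union_all(boxes, grid_size=grid.cell_size * 1e-9)


def home_range(
    grid: ProbabilityGrid,
    level: float = 0.90,
    line: ReferenceLine | None = None,
) -> HomeRange:
    """Extract the home range at an isopleth level from a normalized grid."""
    cells = isopleth_cells(grid, level)
    poly = polygonize(cells, grid)
    area_km2 = len(cells) * (grid.cell_size / 1000.0) ** 2
    mass = float(grid.prob[cells[:, 0], cells[:, 1]].sum())
    hr = HomeRange(poly, level, area_km2, mass, cells=cells)
    if line is not None:
        hr.length_km = length_along_line(hr, line)
    return hr


def length_along_line(hr: HomeRange, line: ReferenceLine) -> float:
    """Arc length (km) of the reference polyline lying inside the home range.

    Disjoint stretches add up; a line entirely outside the polygons gives 0.
    """
    inter = line.as_linestring().intersection(hr.polygons)
    return float(inter.length) / 1000.0
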