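"""Readers and writers for probability grids and polygons.

Grids travel as ESRI ASCII rasters or long-format CSV (x, y, prob); polygons as
GeoJSON or WKT.  All formats are plain text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .home_range import ProbabilityGrid

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_grid_csv",
    "read_grid_csv",
    "write_geojson",
    "read_geojson",
]


def write_ascii_grid(grid: ProbabilityGrid, path) -> None:
    """ESRI ASCII raster; xllcenter/yllcenter anchor the lower-left cell center."""
    header = (
        f"ncols {grid.nx}\n"
        f"nrows {grid.ny}\n"
        f"xllcenter {grid.origin[0]:.6f}\n"
        f"yllcenter {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value -9999\n"
    )
    body = grid.prob[::-1]  # ASCII grids store the north row first
    with open(path, "w") as f:
        f.write(header)
        np.savetxt(f, body, fmt="%.12g")


def read_ascii_grid(path) -> ProbabilityGrid:
    with open(path) as f:
        header: dict[str, float] = {}
        pos = f.tell()
        for _ in range(6):
            pos = f.tell()
            parts = f.readline().split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                f.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        data = np.loadtxt(f)
    nx, ny = int(header["ncols"]), int(header["nrows"])
    cs = header["cellsize"]
    if "xllcenter" in header:
        x0, y0 = header["xllcenter"], header["yllcenter"]
    else:
        x0, y0 = header["xllcorner"] + cs / 2, header["yllcorner"] + cs / 2
    prob = np.atleast_2d(data)[::-1]
    if prob.shape != (ny, nx):
        raise ValueError("ASCII grid body does not match its header dimensions")
    nodata = header.get("nodata_value", -9999.0)
    prob = np.where(prob == nodata, 0.0, prob)
    return ProbabilityGrid((x0, y0), cs, prob, prob <= 0, normalized=True)


def write_grid_csv(grid: ProbabilityGrid, path) -> None:
    c = grid.cell_centers()
    pd.DataFrame({"x": c[:, 0], "y": c[:, 1], "prob": grid.prob.ravel()}).to_csv(
        path, index=False
    )


def read_grid_csv(path) -> ProbabilityGrid:
    df = pd.read_csv(path)
    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    cs = float(np.median(np.diff(xs))) if len(xs) > 1 else float(np.median(np.diff(ys)))
    nx, ny = len(xs), len(ys)
    ix = np.round((df["x"].to_numpy() - xs[0]) / cs).astype(int)
    iy = np.round((df["y"].to_numpy() - ys[0]) / cs).astype(int)
    prob = np.zeros((ny, nx))
    prob[iy, ix] = df["prob"].to_numpy()
    return ProbabilityGrid((float(xs[0]), float(ys[0])), cs, prob, prob <= 0,
                           normalized=True)


def write_geojson(geometry: shapely.Geometry, path, properties: dict | None = None) -> None:
    feature = {
        "type": "Feature",
        "properties": properties or {},
        "geometry": json.loads(shapely.to_geojson(geometry)),
    }
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": [feature]}, indent=1)
    )


def read_geojson(path) -> shapely.Geometry:
    obj = json.loads(Path(path).read_text())
    if obj.get("type") == "FeatureCollection":
        from shapely.ops import unary_union

        return unary_union([shapely.geometry.shape(f["geometry"]) for f in obj["features"]])
    if obj.get("type") == "Feature":
        obj = obj["geometry"]
    return shapely.geometry.shape(obj)
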