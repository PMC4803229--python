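"""Sightings IO, run configuration, and the end-to-end pipeline runner."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gridio
from .estimators import GeographicKDE, PHREEstimator
from .habitat_space import (
    LandPolygons,
    ReferenceLine,
    read_habitat_table,
    read_reference_line,
)
from .landscape_kde import BandwidthSpec, adaptive_bandwidth, mean_nn_distance

log = logging.getLogger("phre")

__all__ = ["RunConfig", "read_sightings", "write_sightings", "run_phre", "load_land"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; serialized into the output directory."""

    sightings: str = ""
    land: str = ""
    line: str = ""
    habitat: str | None = None
    method: str = "phre"
    isopleth_level: float = 0.90
    cell_size: float = 100.0
    pad: float = 5000.0
    seed: int = 0
    bandwidth: dict = field(default_factory=lambda: dataclasses.asdict(BandwidthSpec()))
    kde_h_b: float = 30_000.0
    out_dir: str = "phre_out"

    def bandwidth_spec(self) -> BandwidthSpec:
        return BandwidthSpec(**self.bandwidth)

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def read_sightings(path) -> pd.DataFrame:
    """Read a sightings CSV with columns (id, date, x, y); extra columns kept.

    Rows with non-finite coordinates are rejected with their line numbers —
    silent dropping would mask data problems upstream of the estimator.
    """
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    missing = {"id", "date", "x", "y"} - set(lower)
    if missing:
        raise ValueError(f"sightings file missing required columns: {sorted(missing)}")
    df = df.rename(columns={lower[k]: k for k in ("id", "date", "x", "y")})
    xy = df[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(xy).all(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"non-finite coordinates at file line(s) {lines}")
    df[["x", "y"]] = xy
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_sightings(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_land(path) -> LandPolygons:
    text = Path(path).read_text()
    if text.lstrip().startswith("{"):
        return LandPolygons.from_geojson(text)
    return LandPolygons.from_wkt(text.strip())


def run_phre(config: RunConfig) -> dict:
    """Run the full pipeline and write polygons, grid, and a JSON report.

    Stages: transform -> fit -> back-transform -> isopleth -> polygonize.
    Errors are re-raised with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out / "config.json")

    stage = "read inputs"
    try:
        sightings = read_sightings(config.sightings)
        land = load_land(config.land)
        line = read_reference_line(config.line)
        pts = sightings[["x", "y"]].to_numpy()

        stage = "fit"
        if config.method == "phre":
            est = PHREEstimator(
                line, land, spec=config.bandwidth_spec(),
                cell_size=config.cell_size, pad=config.pad,
                isopleth_level=config.isopleth_level,
            )
        elif config.method == "kde":
            est = GeographicKDE(
                land, h_b=config.kde_h_b, cell_size=config.cell_size,
                pad=config.pad, isopleth_level=config.isopleth_level,
            )
        else:
            raise ValueError(f"unknown method {config.method!r}")
        est.fit(pts)

        if config.method == "phre":
            cps = est.model_.sample[:, 0]
            d = mean_nn_distance(cps) if len(cps) > 1 else float("nan")
            h = adaptive_bandwidth(d, est.spec) if d == d else est.spec.h_b
        else:
            d, h = est.d_geo_, est.h_
        log.info("n=%d  d=%.4f  h=%.4f", len(pts), d, h)

        stage = "back-transform"
        grid = est.probability_grid()
        stage = "isopleth"
        hr = est.home_range(config.isopleth_level)
        stage = "write outputs"
        gridio.write_ascii_grid(grid, out / "probability_grid.asc")
        gridio.write_grid_csv(grid, out / "probability_grid.csv")
        gridio.write_geojson(hr.polygons, out / "home_range.geojson",
                             {"level": config.isopleth_level})
        (out / "home_range.wkt").write_text(hr.polygons.wkt)

        from .evaluation import land_overlap

        report = {
            "method": config.method,
            "n_sightings": int(len(pts)),
            "mean_nn_distance": float(d),
            "bandwidth_h": float(h),
            "isopleth_level": config.isopleth_level,
            "area_km2": hr.area_km2,
            "length_km": hr.length_km,
            "contained_mass": hr.contained_mass,
            "land_overlap_percent": land_overlap(hr, land),
            "seed": config.seed,
        }
        (out / "report.json").write_text(json.dumps(report, indent=1))
        return report
    except Exception as e:
        raise RuntimeError(f"PHRE pipeline failed during stage '{stage}': {e}") from e
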