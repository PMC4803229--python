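"""Estimator-comparison metrics and the ecological shape analysis.

Three protocol metrics compare home-range estimators on the same sightings:

* **Land overlap** — the percent of the home-range polygon's area intersecting
  terrestrial habitat (an estimator that respects the hard boundary scores 0).
* **Sample-size analysis** — home ranges re-estimated on subsamples of N = 10
  to 300 sightings (10 replicates per N, drawn without replacement); the
  minimum adequate N is where mean area becomes statistically indistinguishable
  from the N = 300 estimate (Kruskal-Wallis, then pairwise Wilcoxon rank-sum
  with Bonferroni-adjusted cutoff p = 0.0167), and separately where the fitted
  coefficient-of-variation curve reaches its asymptote.
* **AUC** — probability grids are scored on their ability to rank 100 held-out
  presence sightings above 1,000 pseudo-absence points drawn uniformly from
  within 1 km of the sightings (on water or land), averaged over 10 iterations
  of 200-point fits.  AUC is computed by the Mann-Whitney rank statistic with
  midrank ties, so any strictly monotone transform of the scoring surface
  leaves it unchanged.

The shape analysis regresses log home-range length on log area with a site
term and their interaction, testing whether the length-area slope differs
between sites (elongated vs. compact ranges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import optimize, stats

from .habitat_space import LandPolygons
from .home_range import HomeRange

__all__ = [
    "land_overlap",
    "rank_auc",
    "sample_size_analysis",
    "auc_evaluation",
    "shape_analysis",
    "available_habitat",
    "SampleSizeCurve",
    "AucReport",
    "ShapeReport",
]


def land_overlap(hr: HomeRange, land: LandPolygons) -> float:
    """Percent of home-range area overlapping land: 100 * area(hr ∩ land) / area(hr)."""
    a = hr.polygons.area
    if a <= 0:
        raise ValueError("home range has zero area")
    return 100.0 * hr.polygons.intersection(land.geometry).area / a


def rank_auc(presence_scores: np.ndarray, absence_scores: np.ndarray) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic (midrank ties)."""
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(absence_scores, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# sample-size analysis


@dataclass
class SampleSizeCurve:
    """Replicate home-range areas across subsample sizes, with both minimum-N rules."""

    Ns: np.ndarray
    areas: pd.DataFrame  # columns N, replicate, area_km2
    min_N_area: int | None
    min_N_cv: int | None
    cv: pd.Series = field(repr=False)  # CV per N
    cv_fit: dict = field(default_factory=dict)
    kruskal_p: float = float("nan")
    pairwise_p: pd.Series | None = field(default=None, repr=False)


def _cv_curve(N, c, a, b):
    # decays from c + a at small N toward the asymptote c
    return c + a * b / (b + N)


def sample_size_analysis(
    sightings: np.ndarray,
    estimator,
    seed: int = 0,
    Ns: np.ndarray | None = None,
    n_replicates: int = 10,
    level: float = 0.90,
    alpha_adjusted: float = 0.0167,
    cv_tolerance: float = 0.05,
) -> SampleSizeCurve:
    """Subsample the sightings and locate the minimum adequate sample size.

    A single seeded stream drives the subsampling in a fixed order (per N, per
    replicate), so results are bit-for-bit reproducible given (seed, sightings,
    estimator configuration).
    """
    pts = np.atleast_2d(np.asarray(sightings, dtype=float))
    if Ns is None:
        Ns = np.arange(10, 301, 10)
    Ns = np.asarray(Ns, dtype=int)
    if len(pts) < Ns.max():
        raise ValueError(f"need >= {Ns.max()} sightings, got {len(pts)}")
    rng = np.random.default_rng(seed)

    rows = []
    for N in Ns:
        for rep in range(n_replicates):
            idx = rng.choice(len(pts), size=N, replace=False)
            try:
                hr = estimator.fit(pts[idx]).home_range(level)
            except Exception as e:  # noqa: BLE001 - estimator failures are data
                warnings.warn(f"estimator failed at N={N} rep={rep}: {e}", stacklevel=2)
                continue
            rows.append((int(N), rep, hr.area_km2))
    areas = pd.DataFrame(rows, columns=["N", "replicate", "area_km2"])

    groups = [g["area_km2"].to_numpy() for _, g in areas.groupby("N")]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            kruskal_p = float(stats.kruskal(*groups).pvalue)
        if np.isnan(kruskal_p):
            kruskal_p = 1.0
    except ValueError:  # all values identical
        kruskal_p = 1.0

    ref = areas.loc[areas["N"] == Ns.max(), "area_km2"].to_numpy()
    pair_p = {}
    for N in Ns[:-1]:
        a = areas.loc[areas["N"] == N, "area_km2"].to_numpy()
        if len(a) == 0 or np.ptp(np.concatenate([a, ref])) == 0:
            pair_p[int(N)] = 1.0
        else:
            pair_p[int(N)] = float(stats.mannwhitneyu(a, ref).pvalue)
    pair_p[int(Ns.max())] = 1.0
    pairwise = pd.Series(pair_p)

    if kruskal_p >= alpha_adjusted:
        min_N_area = int(Ns.min())  # no detectable heterogeneity anywhere
    else:
        min_N_area = None
        ok = pairwise >= alpha_adjusted
        # smallest N that is non-significant along with every larger N
        for i, N in enumerate(Ns):
            if ok.iloc[i:].all():
                min_N_area = int(N)
                break

    cv = areas.groupby("N")["area_km2"].apply(
        lambda a: a.std(ddof=1) / a.mean() if a.mean() > 0 else 0.0
    )
    min_N_cv, fit_info = _cv_asymptote(Ns, cv.reindex(Ns).to_numpy(), cv_tolerance)
    return SampleSizeCurve(Ns, areas, min_N_area, min_N_cv, cv, fit_info,
                           kruskal_p, pairwise)


def _cv_asymptote(Ns, cv, tol):
    if np.allclose(cv, cv[0]):
        return int(Ns[0]), {"c": float(cv[0]), "a": 0.0, "b": 1.0}
    try:
        p0 = (max(cv[-1], 1e-6), max(cv[0] - cv[-1], 1e-6), float(Ns[len(Ns) // 4]))
        (c, a, b), _ = optimize.curve_fit(
            _cv_curve, Ns.astype(float), cv, p0=p0,
            bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]), maxfev=20_000,
        )
    except RuntimeError:
        return None, {}
    fitted = _cv_curve(Ns.astype(float), c, a, b)
    scale = c if c > 1e-9 else max(cv.max(), 1e-9)
    within = np.abs(fitted - c) <= tol * scale
    n_star = int(Ns[np.argmax(within)]) if within.any() else None
    return n_star, {"c": float(c), "a": float(a), "b": float(b)}


# ---------------------------------------------------------------------------
# AUC protocol


@dataclass
class AucReport:
    aucs: np.ndarray
    mean: float
    sd: float
    n_fit: int = 200
    n_presence: int = 100
    n_absence: int = 1000


def _disk_union_sampler(sightings: np.ndarray, radius: float, rng, n: int) -> np.ndarray:
    """Uniform points on the union of disks of ``radius`` around the sightings."""
    from shapely.ops import unary_union

    region = unary_union(shapely.buffer(shapely.points(sightings), radius, quad_segs=16))
    x0, y0, x1, y1 = region.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        cand = rng.uniform((x0, y0), (x1, y1), size=(4 * n, 2))
        inside = shapely.contains_xy(region, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[inside]])
    return out[:n]


def auc_evaluation(
    sightings: np.ndarray,
    estimator,
    seed: int = 0,
    n_iterations: int = 10,
    n_fit: int = 200,
    n_presence: int = 100,
    n_absence: int = 1000,
    absence_radius: float = 1000.0,
    score_surface=None,
) -> AucReport:
    """Presence / pseudo-absence discrimination of an estimator's grid.

    Per iteration: fit on ``n_fit`` random sightings, hold out ``n_presence``
    disjoint sightings as presences, draw ``n_absence`` pseudo-absences
    uniformly from within ``absence_radius`` of all sightings (water and land
    alike), score every point by probability-grid cell lookup (off-grid points
    score 0), and compute the rank AUC.  ``score_surface`` substitutes an
    arbitrary scoring function (points -> scores), e.g. for chance baselines.
    """
    pts = np.atleast_2d(np.asarray(sightings, dtype=float))
    if len(pts) < n_fit + n_presence:
        raise ValueError(f"need >= {n_fit + n_presence} sightings, got {len(pts)}")
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_iterations):
        perm = rng.permutation(len(pts))
        fit_idx, pres_idx = perm[:n_fit], perm[n_fit : n_fit + n_presence]
        presences = pts[pres_idx]
        absences = _disk_union_sampler(pts, absence_radius, rng, n_absence)
        if score_surface is None:
            grid = estimator.fit(pts[fit_idx]).probability_grid()
            s_pos, s_neg = grid.lookup(presences), grid.lookup(absences)
        else:
            s_pos, s_neg = score_surface(presences, rng), score_surface(absences, rng)
        aucs.append(rank_auc(s_pos, s_neg))
    aucs = np.asarray(aucs)
    return AucReport(aucs, float(aucs.mean()), float(aucs.std(ddof=1)),
                     n_fit, n_presence, n_absence)


# ---------------------------------------------------------------------------
# shape analysis


@dataclass
class ShapeReport:
    slopes: dict[str, float]
    slope_difference: float
    slope_difference_se: float
    interaction_t: float
    interaction_p: float
    model: object = field(repr=False, default=None)


def shape_analysis(table: pd.DataFrame) -> ShapeReport:
    """Test for site differences in the home-range length-area relationship.

    Fits OLS on log(length) ~ log(area) * site for exactly two sites.  The
    interaction coefficient is the difference between site slopes; its t test
    evaluates the homogeneity-of-slopes assumption.  Columns required:
    area_km2, length_km, site.
    """
    import statsmodels.formula.api as smf

    df = table.copy()
    if (df["area_km2"] <= 0).any() or (df["length_km"] <= 0).any():
        raise ValueError("areas and lengths must be positive for the log-log fit")
    sites = sorted(df["site"].unique())
    if len(sites) != 2:
        raise ValueError(f"shape analysis expects exactly 2 sites, got {sites}")
    if (df.groupby("site").size() < 3).any():
        raise ValueError("need >= 3 home ranges per site")
    df["log_length"] = np.log(df["length_km"])
    df["log_area"] = np.log(df["area_km2"])
    fit = smf.ols("log_length ~ log_area * C(site)", data=df).fit()
    inter = [p for p in fit.params.index if p.startswith("log_area:")]
    if len(inter) != 1:
        raise ValueError("singular design: interaction not estimable")
    key = inter[0]
    base_slope = float(fit.params["log_area"])
    diff = float(fit.params[key])
    return ShapeReport(
        slopes={sites[0]: base_slope, sites[1]: base_slope + diff},
        slope_difference=diff,
        slope_difference_se=float(fit.bse[key]),
        interaction_t=float(fit.tvalues[key]),
        interaction_p=float(fit.pvalues[key]),
        model=fit,
    )


# ---------------------------------------------------------------------------
# available habitat


def available_habitat(
    habitat: pd.DataFrame,
    position_interval: tuple[float, float],
    depth_range: tuple[float, float] = (-39.0, 0.0),
    cell_area_km2: float | None = None,
) -> float:
    """Area (km²) of habitat cells within a depth band and coastal-position interval.

    Emulates masking a bathymetry grid to the depth band accessible to benthic
    foragers (default 0 to -39 m) along a stretch of coast.  ``cell_area_km2``
    defaults to the square of the table's nominal 100-m point spacing.
    """
    lo, hi = sorted(position_interval)
    dlo, dhi = sorted(depth_range)
    sel = (
        habitat["coastal_position"].between(lo, hi)
        & habitat["depth_m"].between(dlo, dhi)
    )
    if cell_area_km2 is None:
        cell_area_km2 = 0.01  # 100 m x 100 m
    if not sel.any():
        warnings.warn("no habitat cells match the depth band and interval", stacklevel=2)
        return 0.0
    return float(sel.sum() * cell_area_km2)
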