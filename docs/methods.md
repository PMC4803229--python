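# Methods

## The model

Home-range estimation by kernel density in geographic coordinates fails for
animals whose habitat has hard boundaries: a symmetric kernel centered on a
sea otter 300 m off a rocky coast necessarily places probability on land.
Permissible home range estimation (PHRE) removes the problem at its root by
estimating the utilization density in a *landscape* coordinate system whose
axes are the habitat features the animal navigates by, then mapping the
density back to geography. Habitat that has no landscape image — land, for a
marine species — can receive no probability, so the exclusion is exact by
construction rather than enforced by post-hoc clipping.

The pipeline has four steps:

1. **Habitat axes.** A reference polyline of sequentially indexed points at
   500-m nominal spacing runs along the coast (for California sea otters this
   is the "As The Otter Swims" line on the 10-m isobath). Each sighting is
   assigned a *decimal coastal position* by perpendicular projection onto the
   nearest line segment (a point projecting 1/3 of the way between points 367
   and 368 gets 367.33), and a *distance from shore* as the Euclidean distance
   to the nearest land boundary. Distance is natural-log-transformed; ln is
   the declared base, and since a base change rescales the axis and its
   bandwidth together, results are base-invariant as long as the fixed
   log-distance bandwidth is interpreted on the same base.

2. **Rejection of impermissible points.** A sighting on or inside land has
   distance ≤ 0 and no log-distance; such records raise an error naming the
   offending row rather than being silently dropped, because the method's
   premise is that all sightings are in water.

3. **Kernel density in landscape space.** A product-Gaussian KDE with a
   diagonal bandwidth matrix (bandwidths are kernel standard deviations). The
   coastal axis uses an adaptive bandwidth

       h = h_b · (d / 4)^2.5,    h_b = 2 index units (1 km of coast),

   where d is the mean nearest-neighbor distance between sightings on the
   coastal axis, in index units. Tightly clumped sightings (small d) get a
   narrow kernel, wide-ranging animals a broad one; at d = 4 the rule returns
   the baseline exactly. A floor of h ≥ 0.1 index units guards the degenerate
   d → 0 case, where the formula would collapse the kernel entirely. The
   log-distance axis uses a fixed bandwidth of 0.05 log units. With more than
   two landscape axes (e.g. adding depth) every axis instead uses the
   per-axis normal-reference rule
   h_a = σ_a · (4/(D+2))^(1/(D+4)) · n^(−1/(D+4)); up to six axes are
   supported, and evaluation is always the exact kernel sum (no binning), so
   any accelerated path can be checked against it.

4. **Back-transform and isopleth.** The fitted landscape density is evaluated
   at the landscape image of every water cell center of a regular geographic
   grid (default 100-m cells, 5-km pad around the sightings); land cells get
   0; the grid is normalized to sum to 1. The home range at level q (default
   0.90) is the smallest set of cells whose cumulative probability reaches q,
   taken in decreasing probability order; cells tied with the threshold value
   are all included so the output is order-independent. Selected cells are
   dissolved into polygons, so area is an exact cell count and the zero-on-
   land property survives polygonization exactly. The normalization is over
   the constructed grid, so the grid must cover the support generously; a
   warning fires when more than 0.1% of unnormalized mass sits in the
   outermost cell ring. Home-range *length* is the arc length of the
   reference line inside the polygons.

Note what the back-transform is: the landscape density evaluated on a
geographic lattice and renormalized, without a Jacobian correction for the
coordinate change. This is the method's definition, not an approximation
here, and it means the geographic surface is a habitat-weighted rendering of
the landscape density rather than its exact push-forward measure; on straight
coasts with the default parameters the measured effect on 90% isopleth mass
is about +0.02.

The back-transform requires at least one landscape axis with a one-to-one
geographic mapping (the coastal-position axis); axis sets without a
positional axis are refused as ill-posed.

## The comparator and the harness

The geographic-space KDE comparator applies the same adaptive rule on planar
meters with a baseline of 30,000, isotropically on both axes, and no land
mask — so it spills onto land exactly as a symmetric kernel must. The 30,000
baseline is taken in meters (the only unit the axes carry); on synthetic data
this produces very large bandwidths, so comparisons that need a responsive
comparator pass a smaller `h_b` explicitly. Note the adaptive rule is not
scale-equivariant (h scales by s^2.5 under a dilation by s); equivariance
holds only when bandwidths co-vary linearly with the data.

Both estimators, and any imported third-party estimate (a probability grid,
or a 10–100% isopleth-polygon stack rasterized innermost-level-wins), share
the same isopleth and polygonization machinery, so metric differences are
attributable to the density surfaces alone. Three metrics:

* **Land overlap**: 100 · area(home range ∩ land) / area(home range).
* **Sample-size curves**: for N = 10…300 in steps of 10, 10 subsamples drawn
  without replacement from a single seeded stream in a fixed (per-N,
  per-replicate) order. The minimum adequate N is the smallest N whose area
  distribution, and that of every larger N, is statistically indistinguishable
  from N = 300 (Kruskal-Wallis gate, then pairwise Wilcoxon rank-sum against
  N = 300 at the Bonferroni-adjusted cutoff p = 0.0167). Separately, the
  coefficient of variation per N is fitted with a decaying-to-asymptote curve
  CV(N) = c + a·b/(b+N) (the functional form is a package choice; standard
  asymptotic-regression alternatives fit these curves equally well), and the
  CV criterion is the smallest N where the fitted curve is within 5%
  (relative, config-exposed) of its asymptote c.
* **AUC**: per iteration, fit on 200 random sightings, score 100 disjoint
  held-out sightings (presences) and 1,000 pseudo-absences drawn uniformly by
  area from the union of 1-km disks around all sightings — on water and land
  alike — by probability-grid cell lookup (off-grid points score 0), and
  compute AUC by the Mann-Whitney rank statistic with midrank ties; 10
  iterations, mean ± SD. The rank formulation makes AUC invariant under any
  strictly monotone transform of the scoring surface, which is what renders
  the isopleth-stack rasterization's particular value map immaterial.

The **shape analysis** fits OLS of log(length) on log(area) × site for two
sites. Sites enter in sorted order, so the interaction coefficient is the
second site's slope minus the first's (alphabetically first site is the
baseline); its t test evaluates the homogeneity-of-slopes assumption, and
the coefficient's magnitude is the between-site difference in the length-area
power law. **Available habitat** masks a habitat point table to a depth band
(default 0 to −39 m, the benthic-foraging range) within a coastal-position
interval and reports km² from exact cell counts.

## The synthetic generator

Scenarios build a land polygon whose seaward edge is a straight line, a
sinusoid (amplitude 1,000 m, wavelength 8,000 m), or a peninsula (a Gaussian
land bump protruding 1,000 m seaward), over a 30-km stretch of coast; the
reference line is the land polygon's 500-m buffer boundary resampled to
exact 500-m arc spacing, so every vertex is 500 m from shore by construction;
the habitat table is a 100-m lattice over the water strip with a parametric
shelf (depth = −0.04 · distance, reaching −40 m at 1 km offshore, a typical
nearshore shelf gradient).

Movement models are a Gaussian mixture along the coastal axis times a
Gaussian in log distance (default center exp-mean 800 m offshore, log-sd
0.5; coastal sd per use — ~1.5 index units emulates a concentrated
female-type range, ~5 a wide-ranging male-type range). The inverse map walks
the line to the sampled fractional index and steps along the seaward normal
so the point's distance from shore equals exp(log-distance), then applies a
few corrective iterations against the forward transform. On straight coasts
the round-trip is exact to machine precision; on the sinusoidal coast the
residual error stays below half the line spacing (0.5 index units) for
points within 2 km of the line, which is the documented tolerance. Samples
falling on land are rejected and redrawn, preserving the in-water density up
to renormalization; a rejection rate above 50% is an error.

What the generator does *not* emulate: temporal autocorrelation of sightings
(treated as independent, as the estimator assumes), tides and haul-outs,
observation error, and realistically fractal coastlines. Passing tests
therefore validate the estimator's geometry, calibration, and bookkeeping —
not its behavior under autocorrelated telemetry.

## Numerical choices and problem sizes

* KDE evaluation is the exact O(n·m) kernel sum, chunked to bound memory;
  it matches an independent sum-of-Gaussians oracle to 1e-10 relative error
  in 1–6 dimensions.
* Isopleth ties are all included (order-independence); grid normalization is
  enforced to 1e-9.
* Polyline-projection ties between segments resolve to the lower index.
* Validation suites run the full pipeline on all three coastline kinds with
  20 seeds each at 100-m cells and 3-km pads, and the recovery study at
  n = 1,000 sightings × 20 seeds with 50,000-draw Monte-Carlo mass estimates
  — sizes chosen so the whole suite runs on a laptop in minutes.

## Known limitations

* The adaptive bandwidth rule is calibrated for sparse resight data: mean
  nearest-neighbor distance shrinks roughly like 1/n, so for dense samples
  (n ≳ a few hundred over a few kilometers of coast) the rule bottoms out at
  the h = 0.1 floor and undersmooths wide-ranging movement models; in a
  straight-coast experiment with coastal sd 5 index units and n = 1,000, the
  90% isopleth's true-generator mass drops to ~0.68, while the same pipeline
  fed the exact generator density yields 0.92. Concentrated ranges
  (sd ≈ 1.5) stay within 0.90 ± 0.05. Users with dense data should consider
  the normal-reference rule instead.
* Back-transform fidelity is limited by grid resolution; near shore a 100-m
  cell spans a wide log-distance interval. Halving the cell size changes the
  90% area by under 5% on smooth fixtures.
* The geographic inverse map (generator only) degrades where the coastline's
  radius of curvature approaches the offshore distance; affected draws are
  rejected, slightly truncating the far-offshore tail on tortuous coasts.
* All geometry is planar Euclidean in meters; inputs must already be in a
  projected CRS.
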