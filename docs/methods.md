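# Methods

This note documents the modelling choices, parameter defaults, numerical
conventions and limitations of the `rnahsi` package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Raster model and preprocessing

A `Grid` is a single-band, square-cell, north-up raster in a projected
CRS (metres). Cell values are samples at cell centres; the grid origin is
the upper-left corner of the upper-left cell. Nodata is carried as NaN
internally (an I/O sentinel is translated on read/write), and any
arithmetic with nodata yields nodata. Geographic (degree) CRSs are
rejected with guidance to reproject: every distance, bandwidth and area
in the method is metric.

* **Radiance calibration.** `L = 10⁻¹⁰·DN^e` with `e = 3/2` by default,
  the published absolute calibration convention for the high-resolution
  NTL sensor this workflow targets; the exponent is a parameter because
  other sensors calibrate differently.
* **Normalization domain.** `LJ_nor` uses the min/max over cells inside
  the study-area mask (the union of the census zones), not the full
  scene: a bright cell outside the city must not compress the in-city
  dynamic range. The unmasked alternative is available by passing no
  mask.
* **Vegetation composite.** Per-period vegetation layers are combined by
  per-cell maximum, ignoring nodata (a cell is nodata only if nodata
  everywhere), which suppresses cloud-contaminated lows. Values are then
  clamped to [0, 1]: negative values flag water/bare surfaces and carry
  no extra settlement information (configurable).
* **Resampling.** Bilinear interpolation at target cell centres; a
  target cell whose 2×2 support touches nodata, or that falls outside
  the hull of source centres, becomes nodata. Bilinear interpolation is
  exact on affine surfaces, which the tests exploit as an oracle.

## Settlement index

`HSI = (1 − EVI_max + LJ_nor) / ((1 − LJ_nor) + EVI_max + LJ_nor·EVI_max)`.
The denominator vanishes only at the corner `(LJ_nor, EVI_max) = (1, 0)`;
it is floored at `ε = 1e-9`, so the corner yields a large finite value
(~2/ε) while all regular cells are computed exactly. HSI is increasing in
normalized radiance and decreasing in vegetation, verified by exhaustive
scan.

## Road-network density

* **Kernel.** Quartic (biweight) `K(u) = (3/π)(1−u²)²/h²` for `u = d/h <
  1`, the common GIS convention for line density; it integrates to 1
  over the plane, so Σ(density × cell area) recovers total line length.
* **Line handling.** Polylines are discretized into length-weighted
  sample points at spacing `cell_size/4` (configurable). This is
  midpoint quadrature of the exact line integral; the error is bounded
  by the spacing and the tests drive it below 1e-6 relative by
  tightening the spacing against an independent fine-quadrature oracle.
* **Evaluation paths.** The default `direct` path accumulates exact
  sample-to-cell distances. A `fft` path splats sample mass bilinearly
  onto the cell lattice and convolves with the kernel sampled at cell
  centres; placement error is below half a cell and the two paths agree
  to ~2e-4 relative on realistic scenes. The fft path exists because the
  bandwidth sweep evaluates hundreds of density grids.
* **Edge effects.** No boundary correction (the usual GIS behaviour):
  mass within `h` of the grid edge is partially lost. The
  mass-conservation tests therefore place networks more than `h` from
  the edges.
* **Bandwidth.** Swept 100–5000 m at 100 m steps; for every
  (bandwidth, class) pair the Pearson correlation between per-zone
  density sums and census counts is tabulated. The default selection is
  3000 m — the middle of the stable correlation region — with the
  mean-correlation maximizer reported alongside so the inspection can be
  reproduced; `choose="max_mean_r"` selects it instead.
* **Class weights.** Per-zone, per-class density sums are standardized
  and the correlation matrix eigendecomposed. Components with eigenvalue
  ≥ 1 are retained (Kaiser rule; the leading component always
  qualifies). The raw weight of a class is Σ_k (variance share of
  component k) × |loading| with loadings scaled by √eigenvalue, then
  normalized to sum to 1. The census column is deliberately excluded
  from this matrix: the weights express the shared structure of the road
  classes, and the census enters the workflow later through two explicit
  calibrations; mixing it into the weights would conflate the two roles.

## Calibration and disaggregation

* **Power law.** Zone-mean density against zone-mean composite RND is
  fitted by OLS in log space (`ln density ~ ln RND`), matching the
  straight-line-on-log-axes reading of the relation. Zones with
  non-positive RND or density are dropped with a recorded count. The
  exponent is unit-invariant; the coefficient is not, and is always
  recomputed in the units at hand. Under multiplicative lognormal noise
  the log-space fit is unbiased, which the tests verify by replication.
* **RNAHSI.** `HSI · RND^b` per cell, with `b > 0` required (the method
  presumes density increases with road density) and `RND = 0 → 0`.
* **Zonal statistics.** Cells are assigned to the zone containing their
  centre; a centre exactly on a shared boundary goes to the first zone
  in id order (deterministic tie-break). Area-weighted assignment was
  rejected as harder to oracle-check for no benefit at 100 m cells.
* **Disaggregation modes.** `regression` (default): pixel = slope×index
  + intercept/n_cells, negatives clipped to zero, then the whole surface
  is scaled by the correction factor (actual/estimated total) so the
  study-area total equals the census exactly. The intercept is spread
  uniformly over in-area cells — the least-informative placement of a
  spatially unattributed constant. `proportional` and
  `proportional_by_zone` allocate counts proportionally to the index
  (per zone in the latter, which conserves every zone exactly and falls
  back to uniform spread, with a warning, in a zone whose index is all
  zero). All modes conserve the study-area total to float precision and
  are invariant to uniform rescaling of the index (proportional modes).
* **Accuracy.** MRE and %RMSE as percentages; R² is reported both as
  squared Pearson correlation (primary, the scatter-fit reading) and as
  1 − SSE/SST about the identity line (secondary, penalizes bias).

## Synthetic scenes

The generator emulates the statistical structure the method assumes, not
the cartography of a real city:

1. a multi-centre intensity field (5 Gaussian centres, 3 km scale, on a
   20×20 km, 100 m grid);
2. bent road segments per class, midpoints sampled with probability ∝
   intensity^(1/b_true), 120 segments per class (≈2000 km total, ≈5
   km/km², a realistic urban road density);
3. true density defined as `a·S^b_true` where `S` is the quartic-KDE
   road-length density at the 3000 m reference bandwidth plus a small
   background floor (0.1% of mean S), scaled to a 2,000,000 total
   population. Defining density *from* the smoothed road field (rather
   than placing roads to match a pre-drawn density) makes the zone-level
   power law hold by construction with `b_true = 1.2322`, while the
   surface remains multi-centre because the roads are;
4. NTL: radiance proportional to *visible* activity — density attenuated
   by up to 50% where road density peaks, standing in for underground
   commerce and transit the sensor cannot see — inverted through the
   radiance calibration to DN, blurred with a 300 m Gaussian (sensor
   blooming) and multiplied by lognormal noise (σ = 0.15). With zero
   noise and blur the DN–density link is strictly monotone;
5. vegetation: 23 layers anti-correlated with density but *saturating* —
   vegetation is gone once density exceeds 15% of its maximum, so the
   index separates urban from rural without grading density inside the
   core, as real vegetation indices behave — with seasonal modulation
   and additive jitter;
6. zones: a rectangular partition (74 by default, the order of a large
   city's township count); census counts are the zone integrals of true
   density, rounded by largest remainder so the totals match exactly.

All randomness flows from one integer seed through independent per-layer
sub-streams, so the same seed reproduces a scene bit for bit and adding a
layer never perturbs the others.

What passing tests on these scenes shows: the pipeline recovers a
power-law calibration it was promised, conserves census mass, and gains
accuracy from the road adjustment when NTL genuinely misses
road-correlated activity. What it does not show: performance under
registration error, non-power-law density–road relations, floating
populations, or villages-in-city whose density breaks the road link —
all listed below as limitations.

## Problem sizes and determinism

The default scene is 200×200 cells with 74 zones; the many-scene
comparisons (20 seeds × two index variants) use quarter-size scenes
(100×100 cells, 36 zones, 40 segments/class, 1000 m bandwidth, 8
vegetation layers) with the fft density path — chosen so the full suite
and the acceptance script each complete in well under a minute while
leaving every zone with dozens of cells. Pipeline runs are deterministic
given config and inputs; accuracy reports are byte-identical across
reruns, which the tests assert.

## Known limitations

* No boundary correction in the line KDE (documented volume deficit near
  edges).
* The GeoTIFF reader/writer handles the package's own single-band,
  square-cell, north-up conventions with an EPSG code — not arbitrary
  GeoTIFFs; CRS handling is identifier equality, not datum mathematics.
  Vector input is GeoJSON only; dual-carriageway merging is assumed done
  upstream.
* The printed-weights convention of external studies (rounded, summing
  to slightly under 1) cannot be reproduced exactly by the normalized
  PCA rule; `composite_rnd` accepts a plain weight mapping for such
  comparisons.
* Regression-mode disaggregation inherits the linear calibration's
  misfit where the index–population relation is convex; the proportional
  modes trade that for exact local conservation.
* The model maps resident population as the census defines it; floating
  populations and temporal dynamics are out of scope.
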