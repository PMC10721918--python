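# Methods

## Scope and model

The package reconstructs a pollution-tracking analysis pipeline for
firm-level emission panels: rasterized constant-quality emission indices,
spatial autocorrelation statistics, a cancer-village proximity regression,
and plan-window trend regressions.  The real data this style of analysis
uses (a national firm pollution database) is confidential, so the package
ships a synthetic generator whose parameters are recorded and returned with
every draw; all claims the test suite makes are claims about recovery of
that recorded truth.

## Synthetic data generator

Firm locations follow a Matérn-style cluster process: parent centers uniform
on a planar extent (default 2000 km × 1500 km), offspring Gaussian with sd
`cluster_sd_km` = 30 km, cluster sizes Poisson with mean
`firms_per_cluster_mean`.  Firms keep location, industry (two-digit codes
13–42) and province for the whole panel.  Log emissions of pollutant j are

    ln P_jit = b0_j + β_size·lnsize_it + β_buffer·1[firm within 40 km of a
               village] + s_j·trend(t, east_i) + ε_jit,  ε ~ N(0, noise_sd²)

with defaults β_size = 0.9, β_buffer = 0.2, noise_sd = 0.5 (log scale).  The
trend is piecewise linear in the year, peaking at the 2006 break:
+0.04/yr before, −0.07/yr after, each with a −0.005/yr East differential;
the per-pollutant scale s_j (wastewater 0.6, COD 2.0, SO₂ 0.7) makes COD
both the fastest riser and the steepest decliner, so the 2012 level sits
below 1998 and the ordering of declines is COD ≫ SO₂ ≳ wastewater.  These
values are the package's study conditions; they were chosen once to emulate
the qualitative record (rise to a 2006 peak, net decline, pollutant-specific
control stringency) and are fully configurable.

Cluster-level heterogeneity enters only through an observed covariate
(cluster-specific mean shift of `lnsize`, sd 0.5).  This matters: cancer
villages are sited at jittered centers of the highest-emitting clusters, so
any *unobserved* cluster intercept would confound the buffer coefficient.
With heterogeneity routed through `lnsize`, which the regression controls,
the buffer effect stays identified and coverage experiments are clean.

Province covariates (gdppc, secondary/tertiary shares, urbanization rate,
population intensity, unemployment) are linear province trends plus
year-to-year noise.  The noise is not cosmetic: with near-deterministic
linear covariates, a within-cell regression cannot separate the year trend
from the controls (they span the same one-dimensional space per province),
and trend estimates degenerate — exactly what the zero-noise mode
demonstrates.

Coordinates are generated on the plane and mapped to WGS84 through an
exactly invertible local projection, so the geodesy path (forward/inverse
projection, haversine distances) is exercised end to end.  The buffer
indicator inside the generator uses the same great-circle distance as the
analysis module, so ring assignment and data-generating assignment agree at
the boundary.

What the generator does **not** emulate: real administrative geography,
firm entry/exit, reporting error and censoring in self-reported emissions,
or spatially correlated residual shocks.  Passing recovery tests therefore
show estimator correctness under the stated model, not robustness to those
features.

## Gridding

Equal-area raster with 100 km cells; membership is half-open
([x_left, x_right) × [y_bottom, y_top)), so edge points belong to exactly
one cell.  For real-world coordinates an Albers equal-area conic projection
(spherical form, standard parallels 25°N/47°N, central meridian 105°E) is
implemented in closed form; equal-area is what makes "equal 100 km cells"
meaningful.  Cells without firms are *missing*, not zero — zeros would drag
interpolated surfaces down; a zero-fill mode exists behind a flag for
sensitivity checks.  Out-of-extent firms are excluded and reported, never
silently dropped.

## Modified Shepard interpolation

The canonical construction: for node k, a quadratic nodal function Q_k
(constant term pinned to the node's value) is fitted by weighted least
squares to the Nq = 13 nearest other nodes, with Renka-style weights
[(R_q − d)₊/(R_q d)]² vanishing at the neighbourhood radius; the surface
blends nodal functions with weights [(R_k − d_k)₊/(R_k d_k)]², R_k the
radius enclosing the Nw = 19 nearest nodes.  Properties relied on by the
pipeline and asserted in tests: exactness at nodes, reproduction of any
global quadratic when Nq ≥ 13, partition of unity (constant fields are
reproduced everywhere).  Degenerate inputs degrade deliberately: < 5
neighbours → linear fit, < 2 → constant; coincident nodes with equal values
are merged, conflicting values rejected.  Queries outside every node's
radius return the nearest node's value (relevant only far outside the data
hull).  Negative interpolated levels are clamped to zero before
normalization, since emission levels are physical quantities.

Nq and Nw are configuration, not claims: the neighbourhood sizes and weight
exponents behind any particular published map are generally unstated, so
the defaults here are the standard literature values.

## Index normalization

Min–max pooled over all cells and years per pollutant (default).  The
alternative reading — normalizing each cell over its own history — is
available as `pooling="cell"`, but pooled normalization is the default
because a time series of regional means is only interpretable when one
scale spans all years.  A constant surface normalizes to all zeros with a
warning rather than an error.  Percent changes are plain
100·(s(t1) − s(t0))/s(t0) on the regional mean series.

## Moran statistics

Queen contiguity (8-neighbour), row-standardized, is the default raster
choice; rook and binary variants by flag.  Global I uses the textbook
double-sum form (asserted against an O(n²) oracle to 1e−12); the
permutation p-value is one-sided in the direction of the observed departure
from E[I] = −1/(n−1), with (extreme + 1)/(n_perm + 1) counting.  Local I_i
follows Anselin's definition with m2 = Σz²/n, satisfying Σ_i I_i = n·I
under row standardization (asserted to 1e−10).  Local inference is
conditional permutation: cell i held fixed, its neighbours' values drawn
without replacement from the other n−1 cells, 999 draws by default, seeded.
Cluster labels are the quadrant where pseudo p ≤ α (default 0.05), else
not-significant.  Cells with missing indices are excluded from the weights
graph, not imputed.  Ties (zero deviation or zero lag) fall to the "high"
side of the quadrant split; with continuous data they have measure zero.

## Regressions

Both regression modules share one estimator: OLS with fixed-effect dummy
sets (first level dropped, single intercept), collinear columns pruned by
pivoted QR — redundant FE dummies silently with a report, collinear *named*
covariates as a hard error (except exact duplicates, which are dropped with
a report).  A within-transformation path (iterated group demeaning,
tolerance 1e−12) exists as an internal consistency check; dummy and within
estimates agree to 1e−8 in tests.  Cluster-robust covariance is CR1:
sandwich with factor G/(G−1)·(n−1)/(n−k), the common convention for
"clustered at the grid level"; an independent hand-rolled sandwich verifies
it in the tests.

Firm model: zero emissions under a log outcome are handled by ln(1+P) by
default, with a strict-log mode that drops zeros (used whenever exactness
against a log-linear truth is asserted); both choices are surfaced in the
fit report.  Two covariate presets reflect a genuine ambiguity in how such
models are reported (one includes the export ratio, the other the
unemployment rate); neither is privileged beyond being the default.

Regime model: year enters centered at the window start, which only moves
the intercept but makes the trend coefficient directly interpretable as the
per-year index change.  The East main effect is absorbed by cell fixed
effects; only the year × East interaction is estimable, and it is dropped
with a report when East does not vary.  A "regime shift" is declared when
the trend is significant in both windows with opposite signs.

## Problem sizes and determinism

The demo study uses ≈3,000 firm-years on a 20 × 20 grid with 999
permutations — small enough to run the full pipeline in well under a
minute while leaving every stage non-trivial; recovery studies use 20
replicates at ≈30,000 firm-years (firm model) and 400 cells × 10 years
(grid model), sizes at which 95% CIs are tight enough for coverage checks
to be informative.  All randomness flows through `numpy.random.default_rng`
with explicit seeds; sparse weight matrices are stored in canonical sorted
order so floating-point summation order — and therefore every CSV byte —
is reproducible across reruns.

## Known limitations

- The interpolation neighbourhood parameters of any specific published map
  are unknowable from the map alone; results depend smoothly on Nq/Nw but
  are not invariant to them.
- Min–max indices are sensitive to the single pooled maximum; one extreme
  cell-year rescales the whole panel.  This is a property of the index
  definition, not of the implementation.
- LISA pseudo p-values are not corrected for multiple testing across cells;
  cluster maps are descriptive.
- The buffer design is associational: villages are *placed* near high
  emitters by construction here, and nothing in the regression identifies a
  causal health effect.
- At the demo scale the regional index series are noisy; seed-to-seed
  variation in pollutant-level percent changes is expected and quantified
  only at the recovery-study sizes.
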