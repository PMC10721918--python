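# pollugrid

Tools for tracking industrial pollution across space and time from firm-level
emission records.  The package targets the analysis style used in
environmental-health studies of China's industrial pollution: firm-year
records of wastewater discharge (tons), chemical oxygen demand (COD, kg) and
SO₂ (kg) are rasterized onto an equal-area 100 km × 100 km grid, converted to
constant-quality emission indices, and used to study spatial clustering,
proximity to "cancer villages", and trend regime shifts between the 10th
(2001–2005) and 11th (2006–2010) Five-Year-Plan periods.

It is written for researchers who have (or emulate) a confidential firm
pollution panel: every stage also runs on a built-in synthetic generator with
recorded ground truth, so the whole pipeline is testable without the real
data.

## What it computes

**Constant-quality emission index.**  Firm emissions are summed per grid cell
and year; cells without firms are filled by Modified Shepard scattered-data
interpolation (locally weighted quadratic nodal functions Q_k blended with
compactly supported inverse-distance weights, exact at data cells):

    F(p) = Σ_k W_k(p) Q_k(p) / Σ_k W_k(p),  W_k(p) = [(R_k − d_k)₊ / (R_k d_k)]²

The interpolated level r_ij of pollutant j in cell i is min–max normalized,

    Index_ij = (r_ij − min r) / (max r − min r) ∈ [0, 1],

with the min/max pooled over all cells **and** years per pollutant, so the
index is comparable across space and time.

**Spatial autocorrelation.**  Global Moran's I (expectation −1/(n−1) under
spatial randomness) and Anselin's Local Moran's I with conditional-permutation
pseudo p-values and HH/LL/HL/LH cluster labels, on queen- or rook-contiguity
weights over the raster.

**Cancer-village buffer regression.**  Firms within 40 km of the nearest
village (buffer = 1) are compared with firms in the 40–80 km annulus
(buffer = 0) in an OLS of log emissions on the buffer dummy, its interactions
with the two plan-period dummies, firm/city covariates, and industry + year
fixed effects.

**Regime-shift regression.**  On the cell-year index panel,

    Index_it = α + β₁ year_t × east_i + β₂ year_t + X_kt Γ + λ_i + ε_it

fitted separately per plan window with cell fixed effects and CR1 standard
errors clustered by cell; a contrast report flags sign flips of the trend
between windows.

## Worked example

The numbered scripts under `analysis/` run the demo study (≈3,000 firm-years,
5 firm clusters, 20 × 20 grid of 100 km cells, seed 1):

```bash
python analysis/01_simulate.py
python analysis/02_grid_and_interpolate.py
python analysis/03_autocorrelation.py
python analysis/04_cancer_village_buffers.py
python analysis/05_regime_shifts.py
```

`02_grid_and_interpolate.py` prints the nationwide index change from 1998 to
2012:

```
index percent change 1998 -> 2012 (All cells):
 pollutant  pct_change
       cod   -30.71...
       so2    -5.83...
wastewater    -2.07...
```

All three indices decline over the window, COD most sharply — the generator
builds in a rise to a 2006 peak followed by a steeper decline, strongest for
COD.  `03_autocorrelation.py` reports large positive global Moran's I
(wastewater 0.720 in 1998 → 0.680 in 2012 here): emissions are strongly
spatially clustered, and the LISA map labels 42 cells HH and 145 LL for COD
in 2012.  `04_cancer_village_buffers.py` prints the buffer regression — e.g.
buffer = 0.228 (SE 0.064) for ln wastewater, firms near villages emit
significantly more — and `05_regime_shifts.py` shows the trend regime shift:
the COD index trend is +0.0094/yr (SE 0.0039) in the 10th plan window and
−0.0340/yr (SE 0.0056) in the 11th, a significant sign flip.

Because the demo panel is small, pollutant-level magnitudes move noticeably
with the seed; the parameter-recovery studies in the test suite quantify the
estimators' behaviour across 20 replicates at larger sizes.

The same pipeline runs from a shell via the `pollugrid` CLI
(`pollugrid all --config run.yaml --seed 1 --outdir out/`), with one verb per
stage (`simulate`, `grid`, `interpolate`, `index`, `moran`, `lisa`, `health`,
`regime`).

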