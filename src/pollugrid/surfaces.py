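"""Interpolated emission surfaces and constant-quality indices.

For each pollutant j and year t the non-missing cell aggregates act as nodes
of a Modified Shepard surface; evaluating the surface at every cell centroid
gives the interpolated level r_ij (missing cells filled by interpolation,
node cells reproduced exactly, negative values clamped to zero since levels
are physical quantities).  Levels are then min-max normalized to

    Index_ij = (r_ij - min r) / (max r - min r)

with the min and max pooled over all cells AND all years per pollutant, so
indices are comparable across both space and time; a per-cell-over-time
pooling is available behind ``pooling='cell'``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grid import GridSpec
from .shepard import ModifiedShepard

__all__ = ["build_surface", "build_surfaces", "normalize_indices",
           "regional_series", "index_change"]


def build_surface(aggregates: pd.Series, spec: GridSpec,
                  nq=13, nw=19) -> np.ndarray:
    """Interpolated per-cell emission levels r for one pollutant-year.

    ``aggregates`` is indexed by flat cell index with NaN marking missing
    cells.  Returns an array of length ``spec.n_cells``.
    """
    values = aggregates.to_numpy(dtype=float)
    obs = ~np.isnan(values)
    if not obs.any():
        raise ValueError("all cells missing: no nodes to interpolate from")
    cen = spec.centroids()
    interp = ModifiedShepard(cen[obs], values[obs], nq=nq, nw=nw)
    r = interp(cen)
    r[obs] = values[obs]          # exactness at nodes, untouched by rounding
    return np.clip(r, 0.0, None)


def build_surfaces(aggregates: pd.DataFrame, spec: GridSpec,
                   nq=13, nw=19) -> pd.DataFrame:
    """Surfaces for every (pollutant, year) in a long aggregate table.

    Input columns: cell, year, pollutant, value (NaN = missing).  Output adds
    column ``r`` with the interpolated level.
    """
    out = []
    for (pol, year), sub in aggregates.groupby(["pollutant", "year"]):
        series = sub.set_index("cell")["value"].reindex(
            np.arange(spec.n_cells))
        r = build_surface(series, spec, nq=nq, nw=nw)
        out.append(pd.DataFrame({
            "cell": np.arange(spec.n_cells), "year": year, "pollutant": pol,
            "value": series.to_numpy(), "r": r}))
    return pd.concat(out, ignore_index=True)


def normalize_indices(surfaces: pd.DataFrame,
                      pooling="pooled") -> pd.DataFrame:
    """Min-max normalize interpolated levels to indices in [0, 1].

    ``pooling='pooled'`` (default) takes the min/max over all cells and years
    per pollutant; ``pooling='cell'`` normalizes each cell over its own
    years.  Returns the input plus columns ``index``, ``r_min``, ``r_max``.
    A constant field (max == min) maps to all zeros with a warning.
    """
    if pooling not in ("pooled", "cell"):
        raise ValueError("pooling must be 'pooled' or 'cell'")
    keys = ["pollutant"] if pooling == "pooled" else ["pollutant", "cell"]
    out = surfaces.copy()
    grp = out.groupby(keys)["r"]
    rmin = grp.transform("min")
    rmax = grp.transform("max")
    span = rmax - rmin
    degenerate = span <= 0
    if degenerate.any():
        warnings.warn("constant surface: min == max, indices set to 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(degenerate, 0.0, (out["r"] - rmin) / span)
    out["index"] = idx
    out["r_min"], out["r_max"] = rmin, rmax
    return out


def regional_series(indices: pd.DataFrame,
                    regions: pd.Series) -> pd.DataFrame:
    """Per-year unweighted mean index for All / each region.

    ``regions`` maps flat cell index -> region label ("East",
    "Central & West", ...).  Regions with no cells are omitted with a
    warning.  Returns columns: pollutant, year, region, mean_index.
    """
    df = indices.copy()
    df["region"] = regions.reindex(df["cell"]).to_numpy()
    if df["region"].isna().any():
        raise ValueError("every cell must carry a region label")
    per_region = (df.groupby(["pollutant", "year", "region"])["index"]
                  .mean().reset_index(name="mean_index"))
    overall = (df.groupby(["pollutant", "year"])["index"]
               .mean().reset_index(name="mean_index"))
    overall["region"] = "All"
    out = pd.concat([overall[per_region.columns], per_region],
                    ignore_index=True)
    present = set(out["region"])
    for lab in pd.unique(regions):
        if lab not in present:
            warnings.warn(f"region {lab!r} has no cells; series omitted",
                          stacklevel=2)
    return out.sort_values(["pollutant", "region", "year"],
                           ignore_index=True)


def index_change(series: pd.DataFrame, t0: int, t1: int) -> pd.DataFrame:
    """Percent change of each (pollutant, region) series from t0 to t1.

    Defined as 100 * (s(t1) - s(t0)) / s(t0); rejected when s(t0) is zero.
    """
    wide = series.pivot_table(index=["pollutant", "region"], columns="year",
                              values="mean_index")
    for t in (t0, t1):
        if t not in wide.columns:
            raise ValueError(f"year {t} absent from the series")
    s0, s1 = wide[t0], wide[t1]
    if (s0 == 0).any():
        bad = s0.index[s0 == 0].tolist()
        raise ValueError(f"series value at {t0} is zero for {bad}; "
                         "percent change undefined")
    out = (100.0 * (s1 - s0) / s0).reset_index(name="pct_change")
    out["t0"], out["t1"] = t0, t1
    return out
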