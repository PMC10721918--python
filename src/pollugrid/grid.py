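"""Equal-area raster construction, firm-to-cell assignment and aggregation.

The study area is tiled by square cells (default 100 km x 100 km) in a planar
equal-area coordinate system.  Cell membership uses half-open intervals
[x_left, x_right) x [y_bottom, y_top), so a point on an interior edge belongs
to exactly one cell.  Cells with no firms in a year carry NaN ("missing"), to
be filled by interpolation — not zero, which would bias the surfaces downward
(a zero-fill mode is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import POLLUTANTS

__all__ = ["GridSpec", "build_grid", "assign_cells", "aggregate_emissions",
           "aggregate_panel", "load_province_regions"]


@dataclass
class GridSpec:
    """Raster geometry: origin, cell size (km) and shape.

    ``cell_id`` is ``(row, col)`` with row 0 at the bottom (lowest y).
    """

    x0: float
    y0: float
    cell_size: float
    n_rows: int
    n_cols: int
    projection: object | None = None

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows * self.n_cols < 1:
            raise ValueError("grid must contain at least one cell")

    @property
    def n_cells(self):
        return self.n_rows * self.n_cols

    def cell_index(self, row, col):
        """Flatten (row, col) -> integer index, row-major from the bottom."""
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def centroids(self):
        """Planar centroids of all cells, shape (n_cells, 2), row-major."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        cx = self.x0 + (cols + 0.5) * self.cell_size
        cy = self.y0 + (rows + 0.5) * self.cell_size
        return np.column_stack([cx, cy])

    def frame(self, region_fn=None) -> pd.DataFrame:
        """Cell table: cell, row, col, centroid x/y (+ lon/lat, region)."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        cen = self.centroids()
        out = pd.DataFrame({"cell": np.arange(self.n_cells),
                            "row": rows, "col": cols,
                            "x": cen[:, 0], "y": cen[:, 1]})
        if self.projection is not None:
            lon, lat = self.projection.inverse(cen[:, 0], cen[:, 1])
            out["lon"], out["lat"] = lon, lat
        if region_fn is not None:
            out["region"] = [region_fn(x, y) for x, y in cen]
        return out


def build_grid(extent, cell_size=100.0, projection=None) -> GridSpec:
    """Tile a planar extent (x0, y0, x1, y1) with square cells.

    The grid covers the extent completely; the last row/column may overhang
    when the extent is not a multiple of ``cell_size``.
    """
    x0, y0, x1, y1 = map(float, extent)
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"degenerate extent {extent}")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    n_cols = int(np.ceil((x1 - x0) / cell_size - 1e-9))
    n_rows = int(np.ceil((y1 - y0) / cell_size - 1e-9))
    return GridSpec(x0=x0, y0=y0, cell_size=cell_size,
                    n_rows=n_rows, n_cols=n_cols, projection=projection)


def assign_cells(firms: pd.DataFrame, spec: GridSpec,
                 x="x", y="y") -> tuple[pd.Series, pd.DataFrame]:
    """Map each firm-year row to its cell index (half-open convention).

    Returns ``(cells, excluded)``: ``cells`` is an integer Series aligned with
    ``firms`` (−1 for out-of-extent rows) and ``excluded`` is the exclusion
    report listing the dropped rows with their coordinates.
    """
    px = firms[x].to_numpy(dtype=float)
    py = firms[y].to_numpy(dtype=float)
    col = np.floor((px - spec.x0) / spec.cell_size).astype(int)
    row = np.floor((py - spec.y0) / spec.cell_size).astype(int)
    inside = ((col >= 0) & (col < spec.n_cols)
              & (row >= 0) & (row < spec.n_rows))
    cells = np.where(inside, spec.cell_index(row, col), -1)
    out = firms.loc[~inside]
    report_cols = [c for c in ("firm_id", "year", x, y) if c in firms.columns]
    excluded = out[report_cols].reset_index(drop=True)
    return pd.Series(cells, index=firms.index, name="cell"), excluded


def aggregate_emissions(firms: pd.DataFrame, cells: pd.Series, pollutant: str,
                        year: int, spec: GridSpec,
                        empty="missing") -> pd.Series:
    """Per-cell pollutant totals for one year.

    A cell with no firms is NaN under ``empty='missing'`` (the default, fed
    to interpolation) or 0.0 under ``empty='zero'``.  Grand totals over cells
    equal the sum over included firms exactly.
    """
    if pollutant not in POLLUTANTS:
        raise ValueError(f"unknown pollutant {pollutant!r}; "
                         f"expected one of {POLLUTANTS}")
    if empty not in ("missing", "zero"):
        raise ValueError("empty must be 'missing' or 'zero'")
    mask = (firms["year"].to_numpy() == year) & (cells.to_numpy() >= 0)
    sub = firms.loc[mask, pollutant]
    totals = np.full(spec.n_cells, np.nan)
    if mask.any():
        sums = pd.Series(sub.to_numpy()).groupby(
            cells.to_numpy()[mask]).sum()
        totals[sums.index.to_numpy()] = sums.to_numpy()
    if empty == "zero":
        totals = np.nan_to_num(totals, nan=0.0)
    return pd.Series(totals, index=np.arange(spec.n_cells), name=pollutant)


def aggregate_panel(firms: pd.DataFrame, cells: pd.Series, spec: GridSpec,
                    pollutants=POLLUTANTS, empty="missing") -> pd.DataFrame:
    """Long cell-year-pollutant aggregate table over the whole panel."""
    frames = []
    for year in sorted(firms["year"].unique()):
        for pol in pollutants:
            agg = aggregate_emissions(firms, cells, pol, int(year), spec,
                                      empty=empty)
            frames.append(pd.DataFrame({
                "cell": agg.index, "year": int(year), "pollutant": pol,
                "value": agg.to_numpy()}))
    return pd.concat(frames, ignore_index=True)


def load_province_regions(path) -> pd.DataFrame:
    """Read an editable province -> region lookup CSV."""
    df = pd.read_csv(path)
    missing = {"province", "region"} - set(df.columns)
    if missing:
        raise ValueError(f"lookup is missing columns: {sorted(missing)}")
    return df
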