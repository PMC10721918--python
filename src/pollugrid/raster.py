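"""Raster export: georeferenced GeoTIFF plus PNG previews.

GeoTIFFs are written with tifffile, attaching the ModelPixelScale,
ModelTiepoint and GeoKeyDirectory tags directly (one float64 band, nodata
-9999, row 0 at the top / highest y).  Index layers get a monotone palette
preview; LISA layers get the categorical HH/LL/HL/LH palette with grey for
not-significant cells.
"""

from __future__ import annotations

import numpy as np
import tifffile
from PIL import Image

from .grid import GridSpec

__all__ = ["layer_to_array", "export_heatmap", "export_lisa_png",
           "read_geotiff", "NODATA", "LISA_COLORS"]

NODATA = -9999.0

#: Classic LISA palette: HH red, LL blue, HL pale red, LH pale blue.
LISA_COLORS = {
    "HH": (215, 25, 28),
    "LL": (44, 123, 182),
    "HL": (253, 174, 97),
    "LH": (171, 217, 233),
    "not-significant": (200, 200, 200),
}


def layer_to_array(values, spec: GridSpec) -> np.ndarray:
    """Flat per-cell values (row-major, row 0 at the bottom) -> 2-D array
    with row 0 at the top, as rasters are stored."""
    a = np.asarray(values, dtype=float).reshape(spec.n_rows, spec.n_cols)
    return a[::-1]


def export_heatmap(values, spec: GridSpec, path, png_path=None,
                   cmap="YlOrRd"):
    """Write one layer as GeoTIFF (and optionally a PNG preview).

    NaNs become the documented nodata value in the GeoTIFF and transparent
    pixels in the PNG.
    """
    img = layer_to_array(values, spec)
    band = np.where(np.isnan(img), NODATA, img).astype(np.float64)
    # GeoTIFF georeferencing: pixel scale + tiepoint at the top-left corner.
    top = spec.y0 + spec.n_rows * spec.cell_size
    scale = (spec.cell_size, spec.cell_size, 0.0)
    tiepoint = (0.0, 0.0, 0.0, spec.x0, top, 0.0)
    geokeys = (1, 1, 0, 3,            # version, rev, minor, number of keys
               1024, 0, 1, 1,         # GTModelTypeGeoKey = projected
               1025, 0, 1, 1,         # GTRasterTypeGeoKey = PixelIsArea
               3076, 0, 1, 9036)      # ProjLinearUnitsGeoKey = kilometre
    extratags = [
        (33550, "d", 3, scale, True),       # ModelPixelScaleTag
        (33922, "d", 6, tiepoint, True),    # ModelTiepointTag
        (34735, "H", len(geokeys), geokeys, True),  # GeoKeyDirectoryTag
        (42113, "s", 0, str(NODATA), True),  # GDAL_NODATA
    ]
    tifffile.imwrite(path, band, extratags=extratags)
    if png_path is not None:
        import matplotlib
        finite = img[~np.isnan(img)]
        lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 1.0)
        norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        rgba = (matplotlib.colormaps[cmap](np.nan_to_num(norm)) * 255)
        rgba[..., 3] = np.where(np.isnan(img), 0, 255)
        Image.fromarray(rgba.astype(np.uint8), "RGBA").save(png_path)


def export_lisa_png(labels, spec: GridSpec, path, scale=16):
    """Categorical LISA cluster map as a paletted PNG.

    Uses exactly the five LISA colours (4 quadrant classes plus
    not-significant); ``scale`` enlarges cells to visible pixels.
    """
    order = list(LISA_COLORS)
    code = {lab: i for i, lab in enumerate(order)}
    flat = np.array([code[str(lab)] for lab in labels], dtype=np.uint8)
    img = flat.reshape(spec.n_rows, spec.n_cols)[::-1]
    img = np.kron(img, np.ones((scale, scale), dtype=np.uint8))
    pil = Image.fromarray(img, "P")
    palette = [c for lab in order for c in LISA_COLORS[lab]]
    pil.putpalette(palette + [0] * (768 - len(palette)))
    pil.save(path)


def read_geotiff(path):
    """Read back a GeoTIFF written by :func:`export_heatmap`.

    Returns ``(array, transform)`` where nodata pixels are NaN and
    ``transform`` is ``(x0, top_y, cell_size)``.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        a = page.asarray().astype(float)
        scale = page.tags[33550].value
        tie = page.tags[33922].value
    a[a == NODATA] = np.nan
    return a, (tie[3], tie[4], scale[0])
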