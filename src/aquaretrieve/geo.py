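"""Minimal georeferencing and GeoTIFF I/O.

Rasters are float32/uint8/uint16 grids with an affine transform, a CRS label
and a nodata sentinel.  Files are written as GeoTIFFs through :mod:`tifffile`,
carrying the standard ModelPixelScale / ModelTiepoint tags plus the GDAL
nodata tag so ordinary GIS readers pick up the georeferencing, and a JSON
ImageDescription with the full metadata (transform, CRS, units, band names,
provenance) for lossless round trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

# GeoTIFF / GDAL private TIFF tags
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class Affine:
    """Row-major affine georeference: ``x = c + a*col``, ``y = f + e*row``.

    ``a`` is the pixel width (> 0), ``e`` the pixel height (negative for
    north-up rasters).  Rotation terms are not supported.  Pixel (row, col)
    indices are 0-based; the georeferenced position of a pixel is its center;
    windows are half-open.
    """

    a: float  # pixel width (x size)
    c: float  # x of the *outer corner* of pixel (0, 0)
    e: float  # pixel height (signed; negative = north-up)
    f: float  # y of the outer corner of pixel (0, 0)

    @property
    def pixel_size(self) -> float:
        return abs(self.a)

    def xy(self, row, col):
        """Map pixel indices to the georeferenced center of that pixel."""
        x = self.c + (np.asarray(col) + 0.5) * self.a
        y = self.f + (np.asarray(row) + 0.5) * self.e
        return x, y

    def rowcol(self, x, y):
        """Map coordinates to the pixel indices containing them (floor rule)."""
        col = np.floor((np.asarray(x) - self.c) / self.a).astype(int)
        row = np.floor((np.asarray(y) - self.f) / self.e).astype(int)
        return row, col

    def to_list(self) -> list[float]:
        return [self.a, self.c, self.e, self.f]

    @classmethod
    def from_list(cls, v: Sequence[float]) -> "Affine":
        return cls(*[float(x) for x in v])


def write_geotiff(
    path: str | Path,
    grid: np.ndarray,
    transform: Affine,
    crs: str,
    nodata: float | int | None,
    metadata: Mapping | None = None,
    band_names: Sequence[str] | None = None,
) -> Path:
    """Write a 2-D grid (or band-stack with shape (bands, rows, cols))."""
    path = Path(path)
    grid = np.asarray(grid)
    meta = dict(metadata or {})
    meta.update(
        {
            "transform": transform.to_list(),
            "crs": crs,
            "nodata": None if nodata is None else float(nodata),
        }
    )
    if band_names is not None:
        meta["band_names"] = list(band_names)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(transform.a), abs(transform.e), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)),
    ]
    if nodata is not None:
        nodata_ascii = repr(float(nodata)) if isinstance(nodata, float) else str(nodata)
        extratags.append((_TAG_GDAL_NODATA, "s", 0, nodata_ascii))
    tifffile.imwrite(
        path,
        grid,
        description=json.dumps(meta),
        extratags=extratags,
        photometric="minisblack",
    )
    return path


def read_geotiff(path: str | Path) -> tuple[np.ndarray, Affine, str, float | None, dict]:
    """Read a raster written by :func:`write_geotiff`.

    Returns (grid, transform, crs, nodata, metadata).  Also understands plain
    GeoTIFFs written by other tools (geo tags only, no JSON description).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        grid = tif.asarray()
        meta: dict = {}
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (ValueError, TypeError):
                meta = {}
        if "transform" in meta:
            transform = Affine.from_list(meta["transform"])
        else:
            scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
            tie = page.tags.get(_TAG_MODEL_TIEPOINT)
            if scale is None or tie is None:
                raise ValueError(f"{path}: no georeferencing found")
            sx, sy = scale.value[0], scale.value[1]
            ox, oy = tie.value[3], tie.value[4]
            transform = Affine(a=float(sx), c=float(ox), e=-float(sy), f=float(oy))
        crs = meta.get("crs", "unknown")
        nodata = meta.get("nodata")
        if nodata is None:
            nd_tag = page.tags.get(_TAG_GDAL_NODATA)
            if nd_tag is not None:
                try:
                    nodata = float(nd_tag.value)
                except ValueError:
                    nodata = None
    return grid, transform, crs, nodata, meta
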