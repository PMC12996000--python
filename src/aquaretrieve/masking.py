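"""Valid-water masking: NDWI thresholding, GMM cutoff selection, quality
layers, boundary buffering, and logical mask combination.

The final validity semantics used by the pipeline are: valid = water evidence
(NDWI threshold and/or rasterized boundary) AND NOT cloud/shadow (SCL or
QA_PIXEL) — quality masks always intersect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize, stats
from sklearn.mixture import GaussianMixture

from .errors import ValidationError
from .geo import read_geotiff, write_geotiff
from .ingest import SceneStack

#: Sen2Cor SCL classes masked by default: 0 no-data, 1 saturated/defective,
#: 3 cloud shadow, 8 cloud medium prob., 9 cloud high prob., 10 thin cirrus.
DEFAULT_SCL_INVALID = frozenset({0, 1, 3, 8, 9, 10})
SCL_WATER_CLASS = 6

#: Landsat Collection-2 QA_PIXEL bits masked by default:
#: 0 fill, 1 dilated cloud, 2 cirrus, 3 cloud, 4 cloud shadow.
DEFAULT_QA_PIXEL_INVALID_BITS = frozenset({0, 1, 2, 3, 4})


@dataclass
class WaterMask:
    """Boolean valid-water grid aligned to a scene, with provenance labels."""

    grid: np.ndarray
    provenance: frozenset[str] = frozenset()
    threshold_used: float | None = None
    warning: str | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        self.provenance = frozenset(self.provenance)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def count(self) -> int:
        return int(self.grid.sum())

    def to_geotiff(self, path: str | Path, scene: SceneStack) -> Path:
        return write_geotiff(
            path,
            self.grid.astype(np.uint8),
            scene.transform,
            scene.crs,
            nodata=255,
            metadata={
                "kind": "water_mask",
                "provenance": sorted(self.provenance),
                "threshold_used": self.threshold_used,
            },
        )

    @classmethod
    def from_geotiff(cls, path: str | Path) -> "WaterMask":
        grid, _, _, _, meta = read_geotiff(path)
        return cls(
            grid=grid == 1,
            provenance=frozenset(meta.get("provenance", [])),
            threshold_used=meta.get("threshold_used"),
        )


@dataclass(frozen=True)
class GmmFit:
    """Two-component univariate Gaussian mixture with an equal-density cutoff."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    threshold: float
    warning: str | None = None


def compute_ndwi(scene: SceneStack) -> np.ndarray:
    """McFeeters NDWI = (green − nir)/(green + nir); positive over open water.

    NaN where the denominator is ≤ 0 or either input is nodata.
    """
    green = scene.band("green").astype(np.float64)
    nir = scene.band("nir").astype(np.float64)
    denom = green + nir
    with np.errstate(invalid="ignore", divide="ignore"):
        ndwi = np.where(denom > 0, (green - nir) / denom, np.nan)
    return ndwi


def fit_gmm_threshold(values: np.ndarray, seed: int = 0) -> GmmFit:
    """Fit a 2-component GMM to an index sample and locate the cutoff.

    The threshold is the equal weighted-component-density crossing between the
    two component means, found by bisection (midpoint of the means when the
    weights and variances are equal).  Deterministic for a fixed seed.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    values = values[np.isfinite(values)]
    if values.size < 100:
        raise ValidationError("need at least 100 finite values for GMM thresholding")

    warning = None
    if np.ptp(values) == 0:
        return GmmFit(
            weights=(1.0, 0.0), means=(values[0], values[0]),
            sds=(0.0, 0.0), threshold=float(values[0]),
            warning="no bimodal structure: constant sample",
        )

    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3,
                         covariance_type="full")
    gm.fit(values[:, None])
    order = np.argsort(gm.means_.ravel())
    w = gm.weights_.ravel()[order]
    m = gm.means_.ravel()[order]
    s = np.sqrt(gm.covariances_.reshape(-1)[order])

    if w.min() < 0.02:
        warning = "no bimodal structure: minor component weight < 0.02"

    def density_gap(x: float) -> float:
        return (w[0] * stats.norm.pdf(x, m[0], s[0])
                - w[1] * stats.norm.pdf(x, m[1], s[1]))

    lo, hi = float(m[0]), float(m[1])
    if hi - lo < 1e-12:
        threshold = 0.5 * (lo + hi)
        warning = warning or "no bimodal structure: coincident component means"
    else:
        # Near each mean its own component dominates, so the gap changes sign
        # on (m0, m1) for any genuinely bimodal fit; fall back to the
        # weighted midpoint otherwise.
        eps = 1e-9 * max(1.0, hi - lo)
        a, b = lo + eps, hi - eps
        if density_gap(a) * density_gap(b) < 0:
            threshold = float(optimize.brentq(density_gap, a, b, xtol=1e-6))
        else:
            threshold = 0.5 * (lo + hi)
            warning = warning or "no bimodal structure: no density crossing"

    return GmmFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(m[0]), float(m[1])),
        sds=(float(s[0]), float(s[1])),
        threshold=threshold,
        warning=warning,
    )


def threshold_mask(index_grid: np.ndarray, cutoff: float) -> WaterMask:
    """True where the index is finite and strictly above the cutoff."""
    grid = np.asarray(index_grid, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        mask = np.isfinite(grid) & (grid > cutoff)
    return WaterMask(grid=mask, provenance={"ndwi"}, threshold_used=float(cutoff))


def decode_scl(scl: np.ndarray, invalid_classes: frozenset[int] = DEFAULT_SCL_INVALID,
               require_water: bool = False) -> WaterMask:
    """Sentinel-2 Scene Classification Layer → validity mask.

    False wherever SCL is in ``invalid_classes`` (clouds, cirrus and — crucially
    for dark water targets — cloud shadows).  With ``require_water`` only SCL
    class 6 (water) is retained.
    """
    scl = np.asarray(scl).astype(np.int64)
    if scl.size and (scl.min() < 0 or scl.max() > 11):
        raise ValidationError("SCL codes must lie in 0..11")
    valid = ~np.isin(scl, list(invalid_classes))
    if require_water:
        valid &= scl == SCL_WATER_CLASS
    return WaterMask(grid=valid, provenance={"scl"})


def decode_qa_pixel(qa: np.ndarray,
                    invalid_bits: frozenset[int] = DEFAULT_QA_PIXEL_INVALID_BITS) -> WaterMask:
    """Landsat Collection-2 QA_PIXEL bit flags → validity mask."""
    qa = np.asarray(qa).astype(np.int64)
    bad = np.zeros(qa.shape, dtype=bool)
    for bit in invalid_bits:
        bad |= (qa >> bit) & 1 == 1
    return WaterMask(grid=~bad, provenance={"qa_pixel"})


def erode_mask(mask: WaterMask, distance_px: int) -> WaterMask:
    """Morphological erosion with an 8-connected (3×3) structuring element.

    Implements the shoreline "negative buffer": a pixel survives iff the
    Chebyshev ball of radius ``distance_px`` around it is entirely true.
    """
    if distance_px < 0:
        raise ValidationError("erosion distance must be >= 0")
    if distance_px == 0:
        return WaterMask(grid=mask.grid.copy(),
                         provenance=mask.provenance | {"buffer"},
                         threshold_used=mask.threshold_used)
    eroded = ndimage.binary_erosion(
        mask.grid, structure=np.ones((3, 3), dtype=bool),
        iterations=distance_px, border_value=0,
    )
    return WaterMask(grid=eroded, provenance=mask.provenance | {"buffer"},
                     threshold_used=mask.threshold_used)


def rasterize_boundary(boundary, buffer_m: float, scene: SceneStack) -> WaterMask:
    """Buffer a water-body polygon (negative shrinks) and rasterize it.

    Pixel-center-in-polygon rule on the scene grid.  The geometry must already
    be in the scene CRS.
    """
    import shapely

    geom = shapely.geometry.shape(boundary) if isinstance(boundary, dict) else boundary
    if buffer_m != 0:
        geom = geom.buffer(buffer_m)
    warning = None
    if geom.is_empty:
        grid = np.zeros(scene.shape, dtype=bool)
        warning = "boundary empty after buffering"
    else:
        rows, cols = scene.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        x, y = scene.transform.xy(rr.ravel(), cc.ravel())
        grid = shapely.contains_xy(geom, x, y).reshape(rows, cols)
    return WaterMask(grid=grid, provenance={"boundary", "buffer"} if buffer_m else {"boundary"},
                     warning=warning)


def combine_masks(masks: list[WaterMask], op: str) -> WaterMask:
    """Per-pixel OR (union) / AND (intersection); provenance is unioned."""
    if not masks:
        raise ValidationError("need at least one mask")
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValidationError(f"mask shapes differ: {shapes}")
    if op == "union":
        grid = np.logical_or.reduce([m.grid for m in masks])
    elif op == "intersection":
        grid = np.logical_and.reduce([m.grid for m in masks])
    else:
        raise ValidationError(f"unknown combine op: {op!r} (use union|intersection)")
    prov = frozenset().union(*[m.provenance for m in masks])
    thresholds = [m.threshold_used for m in masks if m.threshold_used is not None]
    return WaterMask(grid=grid, provenance=prov,
                     threshold_used=thresholds[0] if thresholds else None)
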