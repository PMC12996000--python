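"""Block-wise model application to full scenes and trophic-state products.

Predictions are applied through a rasterized mapping function processed in
square blocks (512×512 by default) so full scenes fit in bounded memory; the
output is independent of the block size and of the number of workers.
Chlorophyll-a maps can be converted to Carlson's Trophic State Index,
TSI = 9.81·ln(chl) + 30.6 (chl in µg/L ≡ mg m⁻³), and classified into trophic
categories with configurable boundaries.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MissingBandError, ValidationError
from .features import FeatureRegistry, compute_feature
from .geo import Affine, read_geotiff, write_geotiff
from .ingest import EXPORT_NODATA, BlockWindow, SceneStack, iter_blocks
from .masking import WaterMask

DEFAULT_BLOCK_SIZE = 512

#: Carlson (1977) chlorophyll-form coefficients.
TSI_CHL_SLOPE = 9.81
TSI_CHL_INTERCEPT = 30.6

#: Default trophic class boundaries: oligo ≤ 40 < meso ≤ 50 < eu ≤ 70 < hyper.
DEFAULT_TSI_THRESHOLDS = (40.0, 50.0, 70.0)
TSI_CLASS_LABELS = ("oligotrophic", "mesotrophic", "eutrophic", "hypereutrophic")


@dataclass
class ConcentrationRaster:
    """Mapped water-quality response (e.g. chl-a in µg/L, turbidity in NTU)."""

    grid: np.ndarray
    transform: Affine
    crs: str
    units: str
    provenance: dict = field(default_factory=dict)
    n_clipped: int = 0  # negative predictions clipped to 0


@dataclass
class TsiRaster:
    """Carlson trophic state index with class assignment."""

    grid: np.ndarray
    class_grid: np.ndarray
    thresholds: tuple[float, ...]
    transform: Affine
    crs: str
    provenance: dict = field(default_factory=dict)


def _model_required_roles(model, registry: FeatureRegistry) -> set[str]:
    roles: set[str] = set()
    for name in model.feature_names:
        roles.update(registry[name].operand_roles)
    return roles


def _block_scene(scene: SceneStack, win: BlockWindow) -> SceneStack:
    sl = win.slices
    return SceneStack(bands={r: g[sl] for r, g in scene.bands.items()},
                      transform=scene.transform, crs=scene.crs,
                      sensor_id=scene.sensor_id)


def map_prediction(scene: SceneStack, mask: WaterMask, model,
                   block_size: int = DEFAULT_BLOCK_SIZE,
                   registry: FeatureRegistry | None = None,
                   n_workers: int = 1, units: str = "") -> ConcentrationRaster:
    """Apply a fitted model to every valid-water pixel of a scene.

    Per block: compute the model's features for mask-true pixels, assemble
    rows, predict, and write back.  Output is NaN outside the mask or where
    any feature is nodata; negative predictions are clipped to 0 and counted.
    Bit-identical across block sizes and worker counts.
    """
    registry = registry or FeatureRegistry.defaults()
    missing = _model_required_roles(model, registry) - set(scene.bands)
    if missing:
        raise MissingBandError(f"missing band: {sorted(missing)[0]}")
    if mask.shape != scene.shape:
        raise ValidationError("mask shape does not match scene")

    out = np.full(scene.shape, np.nan)
    n_clipped = 0
    feature_names = list(model.feature_names)

    def process(win: BlockWindow) -> tuple[BlockWindow, np.ndarray, int]:
        sub = _block_scene(scene, win)
        msub = mask.grid[win.slices]
        block_out = np.full((win.height, win.width), np.nan)
        if not msub.any():
            return win, block_out, 0
        feats = np.stack([
            compute_feature(sub, registry[n]) for n in feature_names
        ])  # (n_features, h, w)
        valid = msub & np.all(np.isfinite(feats), axis=0)
        clipped = 0
        if valid.any():
            X = feats[:, valid].T
            pred = model.predict(X)
            clipped = int(np.sum(pred < 0))
            pred = np.clip(pred, 0, None)
            block_out[valid] = pred
        return win, block_out, clipped

    windows = list(iter_blocks(scene, block_size))
    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(process, windows))
    else:
        results = [process(w) for w in windows]
    for win, block_out, clipped in results:
        out[win.slices] = block_out
        n_clipped += clipped

    prov = {"model": getattr(model, "response_name", "response"),
            "sensor_id": scene.sensor_id,
            "feature_names": feature_names}
    return ConcentrationRaster(grid=out, transform=scene.transform, crs=scene.crs,
                               units=units or getattr(model, "response_name", ""),
                               provenance=prov, n_clipped=n_clipped)


def tsi_from_chla(chl: ConcentrationRaster) -> TsiRaster:
    """Carlson TSI from a chlorophyll-a raster: 9.81·ln(chl) + 30.6.

    Requires µg/L (equivalently mg m⁻³) units; chl ≤ 0 and nodata propagate
    as nodata.
    """
    units = chl.units.lower().replace(" ", "")
    if units not in ("ug/l", "µg/l", "mgm-3", "mg/m3", "mgm⁻³", "chl_a", "chl"):
        raise ValidationError(f"TSI requires chlorophyll in µg/L, got units {chl.units!r}")
    grid = np.asarray(chl.grid, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        tsi = np.where(grid > 0, TSI_CHL_SLOPE * np.log(grid) + TSI_CHL_INTERCEPT, np.nan)
    class_grid = classify_tsi_grid(tsi, DEFAULT_TSI_THRESHOLDS)
    return TsiRaster(grid=tsi, class_grid=class_grid,
                     thresholds=DEFAULT_TSI_THRESHOLDS,
                     transform=chl.transform, crs=chl.crs,
                     provenance=dict(chl.provenance))


def classify_tsi_grid(tsi: np.ndarray, thresholds) -> np.ndarray:
    """Left-open bin lookup: class k iff thresholds[k−1] < TSI ≤ thresholds[k].

    Below the first boundary → class 0; above the last → the last class.
    Nodata pixels get 255.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValidationError("thresholds must be strictly increasing")
    tsi = np.asarray(tsi, dtype=np.float64)
    finite = np.isfinite(tsi)
    cls = np.searchsorted(np.asarray(thresholds), np.nan_to_num(tsi, nan=0.0),
                          side="left").astype(np.uint8)
    cls[~finite] = 255
    return cls


def classify_tsi(tsi: TsiRaster, thresholds=DEFAULT_TSI_THRESHOLDS) -> np.ndarray:
    """Re-classify a TSI raster with custom boundaries (updates class_grid)."""
    cls = classify_tsi_grid(tsi.grid, thresholds)
    tsi.class_grid = cls
    tsi.thresholds = tuple(float(t) for t in thresholds)
    return cls


def export_raster(raster, path: str | Path) -> Path:
    """Write a concentration or TSI raster as a GeoTIFF with nodata + metadata."""
    path = Path(path)
    if isinstance(raster, ConcentrationRaster):
        grid = np.where(np.isfinite(raster.grid), raster.grid, EXPORT_NODATA)
        return write_geotiff(path, grid.astype(np.float32), raster.transform,
                             raster.crs, EXPORT_NODATA,
                             metadata={"kind": "concentration", "units": raster.units,
                                       "provenance": raster.provenance,
                                       "n_clipped": raster.n_clipped})
    if isinstance(raster, TsiRaster):
        grid = np.where(np.isfinite(raster.grid), raster.grid, EXPORT_NODATA)
        out = write_geotiff(path, grid.astype(np.float32), raster.transform,
                            raster.crs, EXPORT_NODATA,
                            metadata={"kind": "tsi",
                                      "thresholds": list(raster.thresholds),
                                      "class_labels": list(TSI_CLASS_LABELS),
                                      "provenance": raster.provenance})
        cls_path = path.with_name(path.stem + "_classes.tif")
        write_geotiff(cls_path, raster.class_grid.astype(np.uint8),
                      raster.transform, raster.crs, 255,
                      metadata={"kind": "tsi_classes",
                                "thresholds": list(raster.thresholds),
                                "class_labels": list(TSI_CLASS_LABELS)})
        legend = path.with_name(path.stem + "_legend.txt")
        bounds = ["-inf"] + [str(t) for t in raster.thresholds]
        lines = [f"{i}\t{label}\t({bounds[i]}, "
                 f"{raster.thresholds[i] if i < len(raster.thresholds) else 'inf'}]"
                 for i, label in enumerate(TSI_CLASS_LABELS[:len(raster.thresholds) + 1])]
        legend.write_text("\n".join(lines) + "\n")
        return out
    raise ValidationError(f"cannot export object of type {type(raster).__name__}")


def read_concentration(path: str | Path) -> ConcentrationRaster:
    grid, transform, crs, nodata, meta = read_geotiff(path)
    grid = grid.astype(np.float64)
    if nodata is not None:
        grid[grid == nodata] = np.nan
    return ConcentrationRaster(grid=grid, transform=transform, crs=crs,
                               units=meta.get("units", ""),
                               provenance=meta.get("provenance", {}),
                               n_clipped=int(meta.get("n_clipped", 0)))
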