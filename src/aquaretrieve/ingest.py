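"""Scene ingestion: declarative band maps, aligned stacks, block iteration.

Scenes are consumed *after* atmospheric correction (ACOLITE GeoTIFF output or
any surface-reflectance product).  A :class:`BandMap` maps sensor-specific file
naming conventions to standard spectral roles; :func:`load_scene` resolves the
map against a directory and resamples every band onto a common grid at the
finest declared resolution (bilinear for reflectance, nearest-neighbour for
categorical quality layers such as SCL / QA_PIXEL, so classes are never mixed).

The module also writes ACOLITE settings files for the external correction step
(:func:`write_acolite_settings`); it never executes ACOLITE.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml
from scipy import ndimage

from .errors import GridConflictError, MissingBandError, ValidationError
from .geo import Affine, read_geotiff, write_geotiff

REFLECTANCE_ROLES = ("blue", "green", "red", "rededge", "nir", "swir1", "swir2")
QUALITY_ROLES = ("scl", "qa_pixel")
ALL_ROLES = REFLECTANCE_ROLES + QUALITY_ROLES

#: Surface reflectance outside this range (tolerating small atmospheric
#: correction overshoot) is treated as nodata.
REFLECTANCE_VALID_RANGE = (-0.05, 1.5)

EXPORT_NODATA = -9999.0  # sentinel used on disk; NaN is used in memory


@dataclass(frozen=True)
class BandEntry:
    role: str
    file_pattern: str
    native_resolution: float
    wavelength: float = 0.0
    scale: float = 1.0
    offset: float = 0.0


@dataclass(frozen=True)
class BandMap:
    """Declarative mapping from file naming conventions to band roles."""

    sensor_id: str
    entries: tuple[BandEntry, ...]

    def __post_init__(self):
        roles = [e.role for e in self.entries]
        if len(set(roles)) != len(roles):
            raise ValidationError(f"duplicate roles in band map {self.sensor_id}")
        for e in self.entries:
            if e.role not in ALL_ROLES:
                raise ValidationError(f"unknown band role: {e.role}")
            if e.role in REFLECTANCE_ROLES and e.scale <= 0:
                raise ValidationError(f"non-positive scale for reflectance role {e.role}")

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(e.role for e in self.entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BandMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            sensor_id=doc["sensor_id"],
            entries=tuple(BandEntry(**e) for e in doc["entries"]),
        )

    @classmethod
    def builtin(cls, sensor_id: str) -> "BandMap":
        """Load one of the band maps shipped with the package (S2MSI, L8OLI)."""
        ref = importlib.resources.files("aquaretrieve.data") / f"{sensor_id}.yml"
        if not ref.is_file():
            raise ValidationError(f"no built-in band map for sensor {sensor_id!r}")
        doc = yaml.safe_load(ref.read_text())
        return cls(sensor_id=doc["sensor_id"], entries=tuple(BandEntry(**e) for e in doc["entries"]))


@dataclass
class SceneStack:
    """Aligned multiband reflectance grid with georeference and band-role map.

    Reflectance bands are float32 with NaN nodata; quality layers keep their
    integer codes (stored as float grids, use :meth:`quality` to decode).
    """

    bands: dict[str, np.ndarray]
    transform: Affine
    crs: str
    sensor_id: str = "unknown"
    nodata: float = float("nan")

    def __post_init__(self):
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise GridConflictError(f"band grids disagree on shape: {shapes}")
        if self.transform.pixel_size <= 0:
            raise ValidationError("transform pixel size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def rows(self) -> int:
        return self.shape[0]

    @property
    def cols(self) -> int:
        return self.shape[1]

    def band(self, role: str) -> np.ndarray:
        if role not in self.bands:
            raise MissingBandError(f"missing band: {role}")
        return self.bands[role]

    def quality(self, role: str) -> np.ndarray:
        """Return a quality layer as integer codes (NaN → 0 / fill)."""
        grid = self.band(role)
        out = np.nan_to_num(grid, nan=0.0)
        return np.rint(out).astype(np.int64)

    def to_geotiff(self, path: str | Path) -> Path:
        roles = list(self.bands)
        stack = np.stack([self.bands[r].astype(np.float32) for r in roles])
        stack = np.where(np.isnan(stack), np.float32(EXPORT_NODATA), stack)
        return write_geotiff(
            path,
            stack,
            self.transform,
            self.crs,
            EXPORT_NODATA,
            metadata={"sensor_id": self.sensor_id, "kind": "scene_stack"},
            band_names=roles,
        )

    @classmethod
    def from_geotiff(cls, path: str | Path) -> "SceneStack":
        grid, transform, crs, nodata, meta = read_geotiff(path)
        names = meta.get("band_names")
        if grid.ndim == 2:
            grid = grid[None]
        if names is None:
            names = [f"band_{i}" for i in range(grid.shape[0])]
        bands = {}
        for name, layer in zip(names, grid.astype(np.float32)):
            layer = layer.copy()
            if nodata is not None and name not in QUALITY_ROLES:
                layer[layer == np.float32(nodata)] = np.nan
            bands[name] = layer
        return cls(bands=bands, transform=transform, crs=crs,
                   sensor_id=meta.get("sensor_id", "unknown"))


@dataclass(frozen=True)
class BlockWindow:
    """Half-open pixel window [row_off, row_off+height) × [col_off, col_off+width)."""

    row_off: int
    col_off: int
    height: int
    width: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row_off, self.row_off + self.height),
            slice(self.col_off, self.col_off + self.width),
        )


def iter_blocks(shape_or_scene, block_size: int) -> Iterator[BlockWindow]:
    """Tile a scene exactly once with row-major, non-overlapping windows.

    Edge windows are ragged (smaller than ``block_size``) so the union of all
    windows covers every pixel exactly once.
    """
    if block_size < 1:
        raise ValidationError("block_size must be >= 1")
    if isinstance(shape_or_scene, SceneStack):
        rows, cols = shape_or_scene.shape
    else:
        rows, cols = shape_or_scene
    for r0 in range(0, rows, block_size):
        for c0 in range(0, cols, block_size):
            yield BlockWindow(r0, c0, min(block_size, rows - r0), min(block_size, cols - c0))


def _resample(grid: np.ndarray, src_res: float, dst_res: float,
              dst_shape: tuple[int, int], order: int) -> np.ndarray:
    """Resample a grid between pixel sizes sharing the same origin corner.

    Pixel-center aligned: target center (i+0.5)*dst maps to source index
    (i+0.5)*dst/src - 0.5.  order=1 bilinear, order=0 nearest.
    """
    if src_res == dst_res and grid.shape == dst_shape:
        return grid.astype(np.float32)
    ratio = dst_res / src_res
    rr = (np.arange(dst_shape[0]) + 0.5) * ratio - 0.5
    cc = (np.arange(dst_shape[1]) + 0.5) * ratio - 0.5
    coords = np.meshgrid(rr, cc, indexing="ij")
    out = ndimage.map_coordinates(
        grid.astype(np.float64), coords, order=order, mode="nearest"
    )
    return out.astype(np.float32)


def load_scene(scene_dir: str | Path, band_map: BandMap,
               target_resolution: float | None = None) -> SceneStack:
    """Resolve a band map against a scene directory into an aligned stack.

    Every band is resampled to ``target_resolution`` (default: the finest
    native resolution declared in the map).  Scale/offset are applied and
    reflectance outside the valid range becomes NaN.
    """
    scene_dir = Path(scene_dir)
    if not scene_dir.is_dir():
        raise ValidationError(f"scene directory not found: {scene_dir}")

    resolved: dict[str, tuple[BandEntry, Path]] = {}
    for entry in band_map.entries:
        hits = sorted(scene_dir.glob(entry.file_pattern))
        if not hits:
            raise MissingBandError(f"missing band: {entry.role}")
        if len(hits) > 1:
            raise ValidationError(
                f"pattern {entry.file_pattern!r} matches {len(hits)} files for role {entry.role}"
            )
        resolved[entry.role] = (entry, hits[0])

    if target_resolution is None:
        target_resolution = min(e.native_resolution for e, _ in resolved.values())

    bands: dict[str, np.ndarray] = {}
    ref_crs = None
    ref_origin = None
    dst_shape = None
    transform = None
    for role, (entry, path) in resolved.items():
        grid, tr, crs, nodata, _ = read_geotiff(path)
        grid = grid.astype(np.float64)
        if nodata is not None and not np.isnan(nodata):
            grid[grid == nodata] = np.nan
        if ref_crs is None:
            ref_crs = crs
        elif crs != ref_crs:
            raise GridConflictError(f"grid conflict: CRS {crs!r} != {ref_crs!r} for {role}")
        origin = (tr.c, tr.f)
        if ref_origin is None:
            ref_origin = origin
        elif not np.allclose(origin, ref_origin):
            raise GridConflictError(f"grid conflict: origin mismatch for {role}")
        if dst_shape is None:
            # scene extent from this band's native geometry
            extent_rows = grid.shape[0] * tr.pixel_size
            extent_cols = grid.shape[1] * tr.pixel_size
            dst_shape = (
                int(round(extent_rows / target_resolution)),
                int(round(extent_cols / target_resolution)),
            )
            transform = Affine(
                a=target_resolution, c=tr.c,
                e=-target_resolution if tr.e < 0 else target_resolution, f=tr.f,
            )
        if role in QUALITY_ROLES:
            out = _resample(np.nan_to_num(grid, nan=0.0), tr.pixel_size,
                            target_resolution, dst_shape, order=0)
        else:
            out = _resample(grid, tr.pixel_size, target_resolution, dst_shape, order=1)
            out = out * entry.scale + entry.offset
            lo, hi = REFLECTANCE_VALID_RANGE
            out = np.where((out < lo) | (out > hi), np.nan, out).astype(np.float32)
        bands[role] = out

    return SceneStack(bands=bands, transform=transform, crs=ref_crs,
                      sensor_id=band_map.sensor_id)


# --- ACOLITE settings generation -------------------------------------------

ACOLITE_METHODS: Mapping[str, str] = {
    "dark_spectrum": "dark_spectrum",
    "radcor": "radcor",
    "exponential": "exponential",
}

_ACOLITE_DEFAULTS = {
    "l2w_parameters": "Rrs_*",
    "l2r_export_geotiff": "True",
    "l2w_export_geotiff": "True",
    "l1r_delete_netcdf": "False",
    "output_geolocation": "True",
}


def write_acolite_settings(l1_dir: str | Path, out_dir: str | Path, method: str,
                           extra: Mapping[str, str] | None = None,
                           settings_path: str | Path | None = None) -> Path:
    """Write a key=value settings file driving an external ACOLITE run.

    Requests surface-reflectance GeoTIFF export alongside ACOLITE's native
    NetCDF output.  ``extra`` overrides any default key.  The file is plain
    ``key=value`` text with ``#`` comments and is parseable back into the
    same mapping with :func:`parse_acolite_settings`.
    """
    if method not in ACOLITE_METHODS:
        raise ValidationError(f"unsupported correction scheme: {method!r}")
    settings = {
        "inputfile": str(Path(l1_dir)),
        "output": str(Path(out_dir)),
        "atmospheric_correction_method": ACOLITE_METHODS[method],
        **_ACOLITE_DEFAULTS,
    }
    if extra:
        settings.update({str(k): str(v) for k, v in extra.items()})
    if settings_path is None:
        settings_path = Path(out_dir) / "acolite_settings.txt"
    settings_path = Path(settings_path)
    settings_path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# ACOLITE settings generated by aquaretrieve"]
    lines += [f"{k}={v}" for k, v in settings.items()]
    settings_path.write_text("\n".join(lines) + "\n")
    return settings_path


def parse_acolite_settings(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
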