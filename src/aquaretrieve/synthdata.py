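"""Synthetic scenes, quality layers and in-situ stations with known truth.

The generator emulates the inputs of a lake or river retrieval campaign: a
land/water/cloud class map, per-class reflectance spectra with Gaussian noise,
SCL and QA_PIXEL layers consistent with the masking conventions, and station
tables whose response follows a known (linear or piecewise-linear) function
of a spectral feature.  Water spectra carry a spatial chlorophyll driver so
the red-edge band — hence NDCI — varies smoothly across the water body.

Default magnitudes mirror a eutrophic-reservoir campaign: 56 stations and a
chlorophyll response spanning roughly 5–75 µg/L, with observation noise at
5 % of the response range.  All randomness flows from one recipe seed via
named substreams (geometry, noise, stations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import ValidationError
from .geo import Affine, write_geotiff
from .ingest import BandEntry, BandMap, SceneStack
from .masking import WaterMask, erode_mask
from .matchup import StationRecord

#: Per-class mean reflectance chosen so NDWI is strongly bimodal
#: (water: green >> nir; land: nir >> green) and NDCI rises with the
#: simulated chlorophyll driver.
DEFAULT_CLASS_SPECTRA = {
    "water": {"blue": 0.040, "green": 0.060, "red": 0.030,
              "rededge": 0.020, "nir": 0.010, "swir1": 0.005},
    "land": {"blue": 0.050, "green": 0.080, "red": 0.100,
             "rededge": 0.200, "nir": 0.350, "swir1": 0.250},
    "cloud": {"blue": 0.350, "green": 0.350, "red": 0.350,
              "rededge": 0.350, "nir": 0.350, "swir1": 0.350},
}

#: Red-edge amplitude added over water as the chl driver goes 0 → 1.
REDEDGE_CHL_AMPLITUDE = 0.030

SCL_WATER, SCL_VEGETATION, SCL_CLOUD_HIGH = 6, 4, 9
QA_CLEAR, QA_CLOUD = 0, 1 << 3  # Collection-2 bit 3 = cloud

DEFAULT_N_STATIONS = 56  # typical single-campaign sample size


@dataclass(frozen=True)
class TruthRelation:
    """Known response = f(feature) relation driving the synthetic truth.

    Piecewise-linear and continuous: ``knots`` are the segment boundaries in
    feature units, ``slopes`` one per segment, anchored at ``y0 = f(knots[0])``.
    """

    feature: str
    knots: tuple[float, ...]
    slopes: tuple[float, ...]
    y0: float

    def __post_init__(self):
        if len(self.slopes) != len(self.knots):
            raise ValidationError("need one slope per knot (segment start)")
        if any(b <= a for a, b in zip(self.knots, self.knots[1:])):
            raise ValidationError("knots must be strictly increasing")

    @classmethod
    def linear(cls, slope: float, intercept: float, feature: str = "NDCI",
               x0: float = 0.0) -> "TruthRelation":
        return cls(feature=feature, knots=(x0,), slopes=(slope,),
                   y0=intercept + slope * x0)

    @classmethod
    def piecewise(cls, knots, slopes, y0: float, feature: str = "NDCI") -> "TruthRelation":
        return cls(feature=feature, knots=tuple(knots), slopes=tuple(slopes), y0=y0)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        y = np.full(x.shape, self.y0)
        # accumulate continuous segments left to right; extrapolate the
        # first/last slope beyond the outer knots
        y = self.y0 + self.slopes[0] * (np.minimum(x, self._knot(1)) - self.knots[0])
        base = self.y0
        for i in range(1, len(self.knots)):
            base += self.slopes[i - 1] * (self.knots[i] - self.knots[i - 1])
            seg = x > self.knots[i]
            upper = self._knot(i + 1)
            y = np.where(seg, base + self.slopes[i] * (np.minimum(x, upper) - self.knots[i]), y)
        return y

    def _knot(self, i: int) -> float:
        return self.knots[i] if i < len(self.knots) else np.inf

    def range_over(self, x: np.ndarray) -> float:
        vals = self(np.asarray(x))
        return float(np.nanmax(vals) - np.nanmin(vals))


def default_chl_relation() -> TruthRelation:
    """Piecewise chl-a vs NDCI spanning roughly 5–75 µg/L over the default scene."""
    return TruthRelation.piecewise(knots=(-0.25, 0.05), slopes=(80.0, 250.0),
                                   y0=1.0, feature="NDCI")


@dataclass
class SceneRecipe:
    seed: int = 0
    rows: int = 256
    cols: int = 256
    pixel_size: float = 10.0
    water_geometry: dict = field(default_factory=lambda: {"kind": "disk", "radius": 60})
    class_spectra: dict = field(default_factory=lambda: DEFAULT_CLASS_SPECTRA)
    noise_sd: float = 0.001
    cloud_fraction: float = 0.0
    truth_relation: TruthRelation = field(default_factory=default_chl_relation)
    obs_noise_fraction: float = 0.05  # station noise as a fraction of response range
    response_name: str = "chl_a"

    def __post_init__(self):
        if not 0 <= self.cloud_fraction <= 1:
            raise ValidationError("cloud_fraction must lie in [0, 1]")
        for cls_name, spectra in self.class_spectra.items():
            if any(v <= 0 for v in spectra.values()):
                raise ValidationError(f"non-positive reflectance in class {cls_name}")


@dataclass
class SyntheticTruth:
    water_mask_truth: np.ndarray
    cloud_mask_truth: np.ndarray
    response_truth: np.ndarray  # NaN outside water
    chl_driver: np.ndarray
    feature_truth: np.ndarray  # the noise-free driving feature (NDCI)
    relation: TruthRelation
    response_name: str = "chl_a"
    station_truth: dict = field(default_factory=dict)


def _water_geometry_mask(recipe: SceneRecipe) -> tuple[np.ndarray, np.ndarray]:
    """Boolean water mask plus the [0, 1] chlorophyll driver field."""
    rows, cols = recipe.rows, recipe.cols
    geo = recipe.water_geometry
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    kind = geo.get("kind", "disk")
    if kind == "disk":
        radius = float(geo.get("radius", min(rows, cols) // 4))
        cr, ccol = geo.get("center", (rows / 2, cols / 2))
        if radius < 1 or radius > min(rows, cols) / 2:
            raise ValidationError("disk radius does not fit the grid")
        dist = np.hypot(rr + 0.5 - cr, cc + 0.5 - ccol)
        water = dist < radius
        # quadratic bloom profile: concentrated in the center, smooth falloff;
        # area-weighted, the driver is then uniform on [0, 1] over the disk
        driver = np.clip(1.0 - (dist / radius) ** 2, 0.0, 1.0)
    elif kind == "river":
        width = float(geo.get("width", rows // 8))
        sinuosity = float(geo.get("sinuosity", 0.5))
        if width < 1 or width > rows:
            raise ValidationError("river width does not fit the grid")
        center = rows / 2 + sinuosity * rows / 4 * np.sin(2 * np.pi * cc / cols)
        water = np.abs(rr + 0.5 - center) < width / 2
        driver = cc / max(cols - 1, 1)
    else:
        raise ValidationError(f"unknown water geometry: {kind!r}")
    return water, np.where(water, driver, 0.0)


def _cloud_mask(recipe: SceneRecipe, rng: np.random.Generator) -> np.ndarray:
    rows, cols = recipe.rows, recipe.cols
    cf = recipe.cloud_fraction
    cloud = np.zeros((rows, cols), dtype=bool)
    if cf <= 0:
        return cloud
    if cf >= 1:
        return np.ones((rows, cols), dtype=bool)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    target = cf * rows * cols
    for _ in range(200):
        if cloud.sum() >= target:
            break
        cr, ccol = rng.uniform(0, rows), rng.uniform(0, cols)
        radius = rng.uniform(0.05, 0.2) * min(rows, cols)
        cloud |= np.hypot(rr - cr, cc - ccol) < radius
    return cloud


def make_scene(recipe: SceneRecipe) -> tuple[SceneStack, np.ndarray, np.ndarray, SyntheticTruth]:
    """Generate (scene, SCL grid, QA_PIXEL grid, truth) from a recipe.

    Per-pixel reflectance = class mean (+ chl driver on the water red edge)
    + N(0, noise_sd²); deterministic for a fixed recipe seed.
    """
    ss = np.random.SeedSequence(recipe.seed)
    geom_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    water, driver = _water_geometry_mask(recipe)
    cloud = _cloud_mask(recipe, geom_rng)

    roles = list(recipe.class_spectra["water"])
    mean = {}
    for role in roles:
        grid = np.where(water, recipe.class_spectra["water"][role],
                        recipe.class_spectra["land"][role]).astype(np.float64)
        if role == "rededge":
            grid = np.where(water, grid + REDEDGE_CHL_AMPLITUDE * driver, grid)
        grid = np.where(cloud, recipe.class_spectra["cloud"][role], grid)
        mean[role] = grid

    # noise-free NDCI over water drives the known response
    with np.errstate(invalid="ignore", divide="ignore"):
        water_rededge = recipe.class_spectra["water"]["rededge"] + REDEDGE_CHL_AMPLITUDE * driver
        water_red = recipe.class_spectra["water"]["red"]
        ndci_truth = np.where(water, (water_rededge - water_red) / (water_rededge + water_red),
                              np.nan)
    response_truth = np.where(water, recipe.truth_relation(np.nan_to_num(ndci_truth)), np.nan)

    bands = {}
    for role in roles:
        noisy = mean[role] + noise_rng.normal(0.0, recipe.noise_sd, size=mean[role].shape)
        bands[role] = noisy.astype(np.float32)

    transform = Affine(a=recipe.pixel_size, c=0.0,
                       e=-recipe.pixel_size, f=recipe.rows * recipe.pixel_size)
    scene = SceneStack(bands=bands, transform=transform, crs="LOCAL:metric",
                       sensor_id="SYNTH")

    scl = np.where(water, SCL_WATER, SCL_VEGETATION).astype(np.int64)
    scl[cloud] = SCL_CLOUD_HIGH
    qa = np.where(cloud, QA_CLOUD, QA_CLEAR).astype(np.int64)

    truth = SyntheticTruth(water_mask_truth=water, cloud_mask_truth=cloud,
                           response_truth=response_truth, chl_driver=driver,
                           feature_truth=ndci_truth, relation=recipe.truth_relation,
                           response_name=recipe.response_name)
    return scene, scl, qa, truth


def make_stations(truth: SyntheticTruth, scene: SceneStack, n: int = DEFAULT_N_STATIONS,
                  seed: int = 0, obs_noise_sd: float | None = None,
                  shore_distance_px: int = 2) -> list[StationRecord]:
    """Sample stations uniformly over interior water pixels.

    Responses are the noise-free truth plus N(0, obs_noise_sd²); by default
    obs_noise_sd is the recipe's observation-noise fraction of the realised
    response range.  Coordinates are pixel centers in the scene CRS.
    """
    if n < 1:
        raise ValidationError("need n >= 1 stations")
    eligible = erode_mask(WaterMask(truth.water_mask_truth), shore_distance_px).grid
    idx = np.flatnonzero(eligible)
    if n > idx.size:
        raise ValidationError(f"{n} stations requested but only {idx.size} eligible pixels")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    chosen = rng.choice(idx, size=n, replace=False)
    rows_idx, cols_idx = np.unravel_index(chosen, truth.water_mask_truth.shape)

    if obs_noise_sd is None:
        resp = truth.response_truth[np.isfinite(truth.response_truth)]
        obs_noise_sd = 0.05 * float(np.ptp(resp)) if resp.size else 0.0

    stations = []
    for i, (r, c) in enumerate(zip(rows_idx, cols_idx)):
        x, y = scene.transform.xy(int(r), int(c))
        true_val = float(truth.response_truth[r, c])
        obs = true_val + (rng.normal(0.0, obs_noise_sd) if obs_noise_sd > 0 else 0.0)
        sid = f"ST{i:03d}"
        truth.station_truth[sid] = true_val
        stations.append(StationRecord(
            sample_id=sid, timestamp="2024-07-15T10:30:00Z",
            lon=float(x), lat=float(y),
            response_name=truth.response_name, response_value=float(obs)))
    return stations


def sample_bimodal(n_per_class: tuple[int, int] = (5000, 5000),
                   means: tuple[float, float] = (-0.5, 0.4),
                   sds: tuple[float, float] = (0.1, 0.1),
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two-component Gaussian sample (fixture for GMM thresholding).

    Returns (values, labels) with label 1 for the upper component.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    a = rng.normal(means[0], sds[0], size=n_per_class[0])
    b = rng.normal(means[1], sds[1], size=n_per_class[1])
    values = np.concatenate([a, b])
    labels = np.concatenate([np.zeros(n_per_class[0], dtype=int),
                             np.ones(n_per_class[1], dtype=int)])
    return values, labels


# --- disk export ------------------------------------------------------------


def synth_band_map(pixel_size: float = 10.0) -> BandMap:
    roles = ["blue", "green", "red", "rededge", "nir", "swir1"]
    entries = [BandEntry(role=r, file_pattern=f"*_{r}.tif",
                         native_resolution=pixel_size) for r in roles]
    entries.append(BandEntry(role="scl", file_pattern="*_scl.tif",
                             native_resolution=pixel_size))
    return BandMap(sensor_id="SYNTH", entries=tuple(entries))


def make_boundary(recipe: SceneRecipe, scene: SceneStack):
    """Shapely polygon of the water body in the scene CRS."""
    from shapely.geometry import Point, Polygon

    geo = recipe.water_geometry
    if geo.get("kind", "disk") == "disk":
        cr, cc = geo.get("center", (recipe.rows / 2, recipe.cols / 2))
        radius_m = float(geo.get("radius", min(recipe.rows, recipe.cols) // 4)) * recipe.pixel_size
        # geometry center in CRS coordinates (grid is corner-anchored)
        x = scene.transform.c + cc * scene.transform.a
        y = scene.transform.f + cr * scene.transform.e
        return Point(x, y).buffer(radius_m, quad_segs=64)
    raise ValidationError("boundary export only supported for disk geometry")


def write_scene_dir(scene: SceneStack, scl: np.ndarray, qa: np.ndarray,
                    truth: SyntheticTruth, stations: list[StationRecord],
                    out_dir: str | Path, recipe: SceneRecipe | None = None) -> Path:
    """Write scene bands, quality layers, truth rasters, boundary and stations."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for role, grid in scene.bands.items():
        write_geotiff(out_dir / f"synth_{role}.tif", grid.astype(np.float32),
                      scene.transform, scene.crs, None)
    write_geotiff(out_dir / "synth_scl.tif", scl.astype(np.uint8),
                  scene.transform, scene.crs, None)
    write_geotiff(out_dir / "synth_qa_pixel.tif", qa.astype(np.uint16),
                  scene.transform, scene.crs, None)
    write_geotiff(out_dir / "truth_water_mask.tif",
                  truth.water_mask_truth.astype(np.uint8),
                  scene.transform, scene.crs, 255)
    resp = np.where(np.isfinite(truth.response_truth), truth.response_truth, -9999.0)
    write_geotiff(out_dir / "truth_response.tif", resp.astype(np.float32),
                  scene.transform, scene.crs, -9999.0)
    pd.DataFrame([{
        "sample_id": s.sample_id, "timestamp": s.timestamp,
        "lon": s.lon, "lat": s.lat, truth.response_name: s.response_value,
    } for s in stations]).to_csv(out_dir / "stations.csv", index=False)
    if recipe is not None and recipe.water_geometry.get("kind", "disk") == "disk":
        from shapely.geometry import mapping

        geom = make_boundary(recipe, scene)
        gj = {"type": "FeatureCollection",
              "features": [{"type": "Feature", "properties": {"name": "water_body"},
                            "geometry": mapping(geom)}]}
        (out_dir / "boundary.geojson").write_text(json.dumps(gj))
    return out_dir
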