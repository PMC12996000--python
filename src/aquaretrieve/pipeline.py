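"""End-to-end workflow orchestration from a single declarative config.

Stages run in workflow order — ingest → mask → features → matchup → fit →
map → TSI — and each stage's product is written to the run directory before
the next starts, so a failure leaves partial products behind and is reported
with the stage name.  Every run writes back the fully resolved configuration
(defaults expanded) and a log of effective parameters and library versions:
the audit artifact for reproducibility.
"""

from __future__ import annotations

import copy
import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ensemble import (ModelSpec, ValidationReport, fit_global, fit_spe, loocv,
                       save_model)
from .errors import AquaRetrieveError, ValidationError
from .features import FeatureRegistry, compute_feature_stack
from .ingest import BandMap, SceneStack, load_scene
from .mapping import (DEFAULT_TSI_THRESHOLDS, classify_tsi, export_raster,
                      map_prediction, tsi_from_chla)
from .masking import (WaterMask, combine_masks, compute_ndwi, decode_qa_pixel,
                      decode_scl, erode_mask, fit_gmm_threshold, threshold_mask)
from .matchup import build_matchup_table, read_stations_csv
from .synthdata import SceneRecipe, TruthRelation, make_scene, make_stations

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "paths": {
        "scene": None,        # pre-built scene stack GeoTIFF
        "scene_dir": None,    # or a directory + sensor band map
        "sensor": None,
        "stations": None,     # station CSV (ignored when synth.enabled)
        "boundary": None,
    },
    "synth": {
        "enabled": False,
        "rows": 256, "cols": 256, "pixel_size": 10.0,
        "geometry": {"kind": "disk", "radius": 60},
        "noise_sd": 0.001, "cloud_fraction": 0.0,
        "n_stations": 56, "obs_noise_fraction": 0.05,
        "truth": {"kind": "piecewise", "feature": "NDCI",
                  "knots": [-0.25, 0.05], "slopes": [80.0, 250.0], "y0": 1.0},
    },
    "masking": {
        "method": "ndwi-gmm",   # ndwi-gmm | ndwi-fixed
        "cutoff": 0.0,           # used by ndwi-fixed
        "erode_px": 1,
        "use_scl": True,
        "use_qa_pixel": True,
        "combine": "intersection",
    },
    "features": {"names": ["NDCI", "NDTI", "BGR"]},
    "matchup": {"window": 3, "stat": "median", "min_valid_fraction": 0.5},
    "model": {
        "kind": "spe",            # lr | rf | svr | spe
        "candidates": ["lr", "rf", "svr"],
        "max_depth": 2, "min_leaf_n": 15, "selection_cv": "kfold",
        "partition_features": None,
        "response": "chl_a",
        "units": "ug/L",
    },
    "mapping": {"block_size": 512, "tsi": True,
                "tsi_thresholds": list(DEFAULT_TSI_THRESHOLDS)},
}


class StageError(AquaRetrieveError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def resolve_config(config: dict | None) -> dict:
    """Expand a partial config against the defaults."""
    cfg = _deep_merge(DEFAULT_CONFIG, config or {})
    if cfg["model"]["kind"] not in ("lr", "rf", "svr", "spe"):
        raise ValidationError(f"unknown model kind: {cfg['model']['kind']!r}")
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


def _truth_relation(tcfg: dict) -> TruthRelation:
    if tcfg["kind"] == "linear":
        return TruthRelation.linear(tcfg["slope"], tcfg["intercept"],
                                    feature=tcfg.get("feature", "NDCI"))
    return TruthRelation.piecewise(tcfg["knots"], tcfg["slopes"], tcfg["y0"],
                                   feature=tcfg.get("feature", "NDCI"))


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None, out_dir: str | Path) -> Path:
    """Execute the full workflow; returns the run directory.

    Stages with pre-computed inputs supplied in the config are skipped (e.g.
    a ready-made scene stack bypasses ingestion).
    """
    cfg = resolve_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.yml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    seed = int(cfg["seed"])
    log: dict = {"stages": [], "versions": _library_versions()}

    scl = qa = truth = None
    stations = None

    # --- ingest / synth -----------------------------------------------------
    stage = "ingest"
    try:
        if cfg["synth"]["enabled"]:
            s = cfg["synth"]
            recipe = SceneRecipe(
                seed=seed, rows=s["rows"], cols=s["cols"], pixel_size=s["pixel_size"],
                water_geometry=s["geometry"], noise_sd=s["noise_sd"],
                cloud_fraction=s["cloud_fraction"],
                truth_relation=_truth_relation(s["truth"]),
                obs_noise_fraction=s["obs_noise_fraction"],
                response_name=cfg["model"]["response"])
            scene, scl, qa, truth = make_scene(recipe)
            resp = truth.response_truth[np.isfinite(truth.response_truth)]
            obs_sd = s["obs_noise_fraction"] * float(np.ptp(resp))
            stations = make_stations(truth, scene, n=s["n_stations"], seed=seed,
                                     obs_noise_sd=obs_sd)
        elif cfg["paths"]["scene"]:
            scene = SceneStack.from_geotiff(cfg["paths"]["scene"])
        elif cfg["paths"]["scene_dir"]:
            if not cfg["paths"]["sensor"]:
                raise ValidationError("scene_dir requires a sensor band map name")
            scene = load_scene(cfg["paths"]["scene_dir"],
                               BandMap.builtin(cfg["paths"]["sensor"]))
        else:
            raise ValidationError("no scene source: set synth.enabled, paths.scene "
                                  "or paths.scene_dir")
        scene.to_geotiff(out_dir / "scene.tif")
        log["stages"].append({"stage": stage, "shape": list(scene.shape)})
    except AquaRetrieveError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, exc)

    # --- mask ---------------------------------------------------------------
    stage = "mask"
    try:
        m = cfg["masking"]
        ndwi = compute_ndwi(scene)
        if m["method"] == "ndwi-gmm":
            sample = ndwi[np.isfinite(ndwi)]
            gmm = fit_gmm_threshold(sample, seed=seed)
            cutoff = gmm.threshold
        elif m["method"] == "ndwi-fixed":
            cutoff = float(m["cutoff"])
        else:
            raise ValidationError(f"unknown masking method: {m['method']!r}")
        parts = [threshold_mask(ndwi, cutoff)]
        if m["use_scl"]:
            if scl is not None:
                parts.append(decode_scl(scl))
            elif "scl" in scene.bands:
                parts.append(decode_scl(scene.quality("scl")))
        if m["use_qa_pixel"]:
            if qa is not None:
                parts.append(decode_qa_pixel(qa))
            elif "qa_pixel" in scene.bands:
                parts.append(decode_qa_pixel(scene.quality("qa_pixel")))
        mask = combine_masks(parts, "intersection")
        if m["erode_px"] > 0:
            mask = erode_mask(mask, int(m["erode_px"]))
        mask.to_geotiff(out_dir / "mask.tif", scene)
        log["stages"].append({"stage": stage, "cutoff": float(cutoff),
                              "valid_pixels": mask.count()})
    except AquaRetrieveError as exc:
        raise StageError(stage, exc) from exc

    # --- features -----------------------------------------------------------
    stage = "features"
    registry = FeatureRegistry.defaults()
    feature_names = list(cfg["features"]["names"])
    try:
        feats = compute_feature_stack(scene, registry, mask, feature_names)
        feats.to_geotiff(out_dir / "features.tif")
        log["stages"].append({"stage": stage, "names": feature_names})
    except AquaRetrieveError as exc:
        raise StageError(stage, exc) from exc

    # --- matchup ------------------------------------------------------------
    stage = "matchup"
    try:
        if stations is None:
            if not cfg["paths"]["stations"]:
                raise ValidationError("model stage requested but no stations "
                                      "provided (paths.stations)")
            stations = read_stations_csv(cfg["paths"]["stations"],
                                         cfg["model"]["response"])
        mu = cfg["matchup"]
        table = build_matchup_table(stations, feats, mask, scene,
                                    window=int(mu["window"]), stat=mu["stat"],
                                    min_valid_fraction=float(mu["min_valid_fraction"]))
        table.to_csv(out_dir / "matchups.csv")
        log["stages"].append({"stage": stage, "n_stations": len(table),
                              "n_usable": len(table.usable_rows())})
    except AquaRetrieveError as exc:
        raise StageError(stage, exc) from exc

    # --- fit ----------------------------------------------------------------
    stage = "fit"
    try:
        mc = cfg["model"]
        if mc["kind"] == "spe":
            candidates = [ModelSpec.make(k, seed=seed) for k in mc["candidates"]]

            def procedure(tbl):
                return fit_spe(tbl, candidates,
                               partition_features=mc["partition_features"],
                               max_depth=int(mc["max_depth"]),
                               min_leaf_n=int(mc["min_leaf_n"]),
                               selection_cv=mc["selection_cv"], seed=seed)
        else:
            spec = ModelSpec.make(mc["kind"], seed=seed)

            def procedure(tbl):
                return fit_global(spec, tbl)

        report = loocv(procedure, table)
        model = procedure(table)
        save_model(model, out_dir / "model.bin")
        report.to_json(out_dir / "report.json")
        log["stages"].append({"stage": stage, "kind": mc["kind"],
                              "report": report.to_dict()})
    except AquaRetrieveError as exc:
        raise StageError(stage, exc) from exc

    # --- map / tsi ----------------------------------------------------------
    stage = "map"
    try:
        raster = map_prediction(scene, mask, model,
                                block_size=int(cfg["mapping"]["block_size"]),
                                registry=registry, units=cfg["model"]["units"])
        export_raster(raster, out_dir / "concentration.tif")
        log["stages"].append({"stage": stage, "n_clipped": raster.n_clipped})
        if cfg["mapping"]["tsi"] and cfg["model"]["units"].lower().startswith(("ug", "µg", "mg")):
            tsi = tsi_from_chla(raster)
            classify_tsi(tsi, cfg["mapping"]["tsi_thresholds"])
            export_raster(tsi, out_dir / "tsi.tif")
            log["stages"].append({"stage": "tsi",
                                  "thresholds": cfg["mapping"]["tsi_thresholds"]})
    except AquaRetrieveError as exc:
        raise StageError(stage, exc) from exc

    log["checksums"] = {p.name: _file_checksum(p)
                        for p in sorted(out_dir.glob("*"))
                        if p.is_file() and p.name != "run_log.json"}
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return out_dir


def _library_versions() -> dict:
    import sklearn
    import scipy
    import pandas

    return {
        "aquaretrieve": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
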