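"""Satellite–in-situ matchup generation.

Each station is georeferenced to its containing pixel and every feature is
summarised over a small window (3×3 or 5×5) centered on that pixel, using a
robust statistic (median by default) over mask-true pixels only.  The result
is a synchronized calibration table: station metadata, predictors, the count
of valid contributing pixels and quality flags.

Station coordinates must be expressed in the scene CRS (projected x/y, or
pixel-center coordinates for local grids); on-the-fly reprojection is out of
scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import FeatureStack
from .ingest import SceneStack
from .masking import WaterMask

FLAG_EDGE = "edge_of_scene"
FLAG_LOW_VALID = "low_valid_fraction"
FLAG_OOB = "out_of_bounds"

DEFAULT_WINDOW = 3
DEFAULT_STAT = "median"
DEFAULT_MIN_VALID_FRACTION = 0.5


@dataclass(frozen=True)
class StationRecord:
    sample_id: str
    timestamp: str
    lon: float  # x in the scene CRS
    lat: float  # y in the scene CRS
    response_name: str
    response_value: float

    def __post_init__(self):
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValidationError(f"station {self.sample_id}: non-finite coordinates")
        if not math.isfinite(self.response_value):
            raise ValidationError(f"station {self.sample_id}: non-finite response")


@dataclass
class MatchupRow:
    station: StationRecord
    predictors: dict[str, float]
    n_valid: int
    flags: frozenset[str]


@dataclass
class MatchupTable:
    rows: list[MatchupRow]
    feature_names: list[str]
    response_name: str

    def __len__(self) -> int:
        return len(self.rows)

    def usable_rows(self, include_flagged: bool = False) -> list[MatchupRow]:
        """Rows fit for model calibration: finite predictors, unflagged by default."""
        out = []
        for row in self.rows:
            if not include_flagged and row.flags:
                continue
            if any(not math.isfinite(row.predictors[n]) for n in self.feature_names):
                continue
            out.append(row)
        return out

    def to_arrays(self, feature_names: list[str] | None = None,
                  include_flagged: bool = False) -> tuple[np.ndarray, np.ndarray]:
        names = feature_names or self.feature_names
        rows = self.usable_rows(include_flagged)
        X = np.array([[r.predictors[n] for n in names] for r in rows], dtype=np.float64)
        y = np.array([r.station.response_value for r in rows], dtype=np.float64)
        if X.size == 0:
            X = X.reshape(0, len(names))
        return X, y

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            rec = {
                "sample_id": row.station.sample_id,
                "timestamp": row.station.timestamp,
                "lon": row.station.lon,
                "lat": row.station.lat,
                self.response_name: row.station.response_value,
            }
            rec.update({n: row.predictors[n] for n in self.feature_names})
            rec["n_valid"] = row.n_valid
            rec["flags"] = ";".join(sorted(row.flags))
            recs.append(rec)
        cols = (["sample_id", "timestamp", "lon", "lat", self.response_name]
                + self.feature_names + ["n_valid", "flags"])
        return pd.DataFrame(recs, columns=cols)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, response_name: str,
                 feature_names: list[str] | None = None) -> "MatchupTable":
        df = pd.read_csv(path, dtype={"sample_id": str, "flags": str})
        meta_cols = {"sample_id", "timestamp", "lon", "lat", response_name,
                     "n_valid", "flags"}
        if feature_names is None:
            feature_names = [c for c in df.columns if c not in meta_cols]
        rows = []
        for _, rec in df.iterrows():
            flags = rec.get("flags", "")
            flags = frozenset(str(flags).split(";")) - {"", "nan"}
            rows.append(MatchupRow(
                station=StationRecord(
                    sample_id=str(rec["sample_id"]), timestamp=str(rec["timestamp"]),
                    lon=float(rec["lon"]), lat=float(rec["lat"]),
                    response_name=response_name,
                    response_value=float(rec[response_name])),
                predictors={n: float(rec[n]) for n in feature_names},
                n_valid=int(rec["n_valid"]), flags=flags))
        return cls(rows=rows, feature_names=list(feature_names),
                   response_name=response_name)


def read_stations_csv(path: str | Path, response_name: str | None = None) -> list[StationRecord]:
    """Read a station table CSV (sample_id, timestamp, lon, lat, value)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "timestamp", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"station CSV missing columns: {sorted(missing)}")
    if response_name is None:
        value_cols = [c for c in df.columns if c not in required]
        if not value_cols:
            raise ValidationError("station CSV has no response column")
        response_name = value_cols[0]
    return [
        StationRecord(
            sample_id=str(r["sample_id"]), timestamp=str(r["timestamp"]),
            lon=float(r["lon"]), lat=float(r["lat"]),
            response_name=response_name, response_value=float(r[response_name]))
        for _, r in df.iterrows()
    ]


def extract_window_stat(grid: np.ndarray, mask: WaterMask | np.ndarray,
                        pixel_rc: tuple[int, int], window: int = DEFAULT_WINDOW,
                        stat: str = DEFAULT_STAT) -> tuple[float, int, frozenset[str]]:
    """Robust statistic of a window centered on a pixel, mask-true pixels only.

    Returns (value, n_valid, flags).  The window is clipped at scene edges
    (flagged ``edge_of_scene``); n_valid = 0 yields NaN with ``out_of_bounds``.
    """
    if window % 2 == 0 or window < 1:
        raise ValidationError("window must be odd and >= 1")
    if stat not in ("median", "mean"):
        raise ValidationError(f"unknown stat: {stat!r}")
    grid = np.asarray(grid, dtype=np.float64)
    mgrid = mask.grid if isinstance(mask, WaterMask) else np.asarray(mask, dtype=bool)
    rows, cols = grid.shape
    r, c = pixel_rc
    if not (0 <= r < rows and 0 <= c < cols):
        return float("nan"), 0, frozenset({FLAG_OOB})
    half = window // 2
    r0, r1 = max(0, r - half), min(rows, r + half + 1)
    c0, c1 = max(0, c - half), min(cols, c + half + 1)
    flags = set()
    if (r1 - r0) < window or (c1 - c0) < window:
        flags.add(FLAG_EDGE)
    patch = grid[r0:r1, c0:c1]
    mpatch = mgrid[r0:r1, c0:c1]
    valid = mpatch & np.isfinite(patch)
    n_valid = int(valid.sum())
    if n_valid == 0:
        flags.add(FLAG_OOB)
        return float("nan"), 0, frozenset(flags)
    vals = patch[valid]
    value = float(np.median(vals) if stat == "median" else np.mean(vals))
    return value, n_valid, frozenset(flags)


def build_matchup_table(stations: list[StationRecord], features: FeatureStack,
                        mask: WaterMask, scene: SceneStack,
                        window: int = DEFAULT_WINDOW, stat: str = DEFAULT_STAT,
                        min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION) -> MatchupTable:
    """Pair stations with windowed feature statistics into a calibration table.

    Stations outside the scene are flagged ``out_of_bounds`` with NaN
    predictors; rows whose valid-pixel fraction falls below
    ``min_valid_fraction`` are flagged ``low_valid_fraction`` (retained, but
    excluded from fitting by default).
    """
    response_names = {s.response_name for s in stations}
    if len(response_names) > 1:
        raise ValidationError(f"mixed response variables in station list: {response_names}")
    response_name = response_names.pop() if response_names else "response"

    rows: list[MatchupRow] = []
    nrows, ncols = scene.shape
    for st in stations:
        r, c = scene.transform.rowcol(st.lon, st.lat)
        r, c = int(r), int(c)
        if not (0 <= r < nrows and 0 <= c < ncols):
            rows.append(MatchupRow(
                station=st,
                predictors={n: float("nan") for n in features.names},
                n_valid=0, flags=frozenset({FLAG_OOB})))
            continue
        predictors = {}
        flags: set[str] = set()
        n_valid_min = window * window
        for name in features.names:
            value, n_valid, f = extract_window_stat(
                features.grids[name], mask, (r, c), window, stat)
            predictors[name] = value
            n_valid_min = min(n_valid_min, n_valid)
            flags |= set(f)
        if n_valid_min / (window * window) < min_valid_fraction:
            flags.add(FLAG_LOW_VALID)
        rows.append(MatchupRow(station=st, predictors=predictors,
                               n_valid=n_valid_min, flags=frozenset(flags)))
    return MatchupTable(rows=rows, feature_names=list(features.names),
                        response_name=response_name)
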