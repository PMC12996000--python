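"""Declarative spectral-feature registry and block-wise feature computation.

Features are simple algebraic combinations of band roles — raw bands,
ratios, differences and normalized differences — declared as data, so new
indices can be added without touching code (via :func:`register_feature` or a
text config).  Built-ins cover the indices commonly used for inland-water
retrievals: NDCI (chlorophyll-a in turbid waters), NDTI (turbidity), the
blue–green ratio (CDOM proxy) and a few band ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import MissingBandError, ValidationError
from .geo import write_geotiff, read_geotiff
from .ingest import REFLECTANCE_ROLES, SceneStack
from .masking import WaterMask

FEATURE_KINDS = ("band", "normalized_difference", "ratio", "difference")


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str
    operand_roles: tuple[str, ...]
    valid_sensors: frozenset[str] = frozenset()  # empty = any sensor

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind: {self.kind!r}")
        n = len(self.operand_roles)
        if self.kind == "band" and n != 1:
            raise ValidationError("band feature takes exactly 1 operand")
        if self.kind != "band" and n != 2:
            raise ValidationError(f"{self.kind} takes exactly 2 operands")


class FeatureRegistry:
    """Ordered, name-unique collection of feature specs."""

    def __init__(self, specs: list[FeatureSpec] | None = None):
        self._specs: dict[str, FeatureSpec] = {}
        for spec in specs or []:
            self.register(spec)

    def register(self, spec: FeatureSpec) -> "FeatureRegistry":
        if spec.name in self._specs:
            raise ValidationError(f"feature already registered: {spec.name}")
        self._specs[spec.name] = spec
        return self

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __getitem__(self, name: str) -> FeatureSpec:
        if name not in self._specs:
            raise ValidationError(f"unknown feature: {name}")
        return self._specs[name]

    def names(self) -> list[str]:
        return list(self._specs)

    def specs(self) -> list[FeatureSpec]:
        return list(self._specs.values())

    def subset(self, names: list[str]) -> "FeatureRegistry":
        return FeatureRegistry([self[n] for n in names])

    @classmethod
    def defaults(cls) -> "FeatureRegistry":
        reg = cls()
        reg.register(FeatureSpec("NDCI", "normalized_difference", ("rededge", "red")))
        reg.register(FeatureSpec("NDTI", "normalized_difference", ("red", "green")))
        reg.register(FeatureSpec("BGR", "ratio", ("blue", "green")))
        reg.register(FeatureSpec("red_nir_ratio", "ratio", ("red", "nir")))
        reg.register(FeatureSpec("green_blue_ratio", "ratio", ("green", "blue")))
        reg.register(FeatureSpec("red_blue_ratio", "ratio", ("red", "blue")))
        for role in REFLECTANCE_ROLES:
            reg.register(FeatureSpec(role, "band", (role,)))
        return reg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls([
            FeatureSpec(d["name"], d["kind"], tuple(d["operands"]),
                        frozenset(d.get("valid_sensors", [])))
            for d in doc["features"]
        ])

    def to_yaml(self, path: str | Path) -> Path:
        doc = {"features": [
            {"name": s.name, "kind": s.kind, "operands": list(s.operand_roles),
             **({"valid_sensors": sorted(s.valid_sensors)} if s.valid_sensors else {})}
            for s in self._specs.values()
        ]}
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path


def register_feature(spec: FeatureSpec, registry: FeatureRegistry) -> FeatureRegistry:
    return registry.register(spec)


def compute_feature(scene: SceneStack, spec: FeatureSpec,
                    mask: WaterMask | None = None) -> np.ndarray:
    """Evaluate one feature over a scene, NaN outside the mask.

    Normalized difference = (a−b)/(a+b); ratio = a/b; difference = a−b.
    NaN where a denominator is ≤ 0 or any operand is nodata.
    """
    if spec.valid_sensors and scene.sensor_id not in spec.valid_sensors:
        raise ValidationError(
            f"feature unavailable for sensor: {spec.name} on {scene.sensor_id}")
    for role in spec.operand_roles:
        if role not in scene.bands:
            raise MissingBandError(
                f"feature unavailable for sensor: {spec.name} needs band {role}")
    ops = [scene.band(r).astype(np.float64) for r in spec.operand_roles]
    with np.errstate(invalid="ignore", divide="ignore"):
        if spec.kind == "band":
            out = ops[0].copy()
        elif spec.kind == "normalized_difference":
            a, b = ops
            denom = a + b
            out = np.where(denom > 0, (a - b) / denom, np.nan)
        elif spec.kind == "ratio":
            a, b = ops
            out = np.where(b > 0, a / b, np.nan)
        else:  # difference
            out = ops[0] - ops[1]
    if mask is not None:
        out = np.where(mask.grid, out, np.nan)
    return out


@dataclass
class FeatureStack:
    """Named, aligned feature grids computed from one scene."""

    names: list[str]
    grids: dict[str, np.ndarray]
    mask_applied: bool
    transform: object = None
    crs: str = "unknown"

    def __post_init__(self):
        shapes = {g.shape for g in self.grids.values()}
        if len(shapes) > 1:
            raise ValidationError(f"feature grids disagree on shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.grids.values())).shape

    def to_geotiff(self, path: str | Path) -> Path:
        from .ingest import EXPORT_NODATA

        stack = np.stack([self.grids[n].astype(np.float32) for n in self.names])
        stack = np.where(np.isnan(stack), np.float32(EXPORT_NODATA), stack)
        return write_geotiff(path, stack, self.transform, self.crs, EXPORT_NODATA,
                             metadata={"kind": "feature_stack",
                                       "mask_applied": self.mask_applied},
                             band_names=self.names)

    @classmethod
    def from_geotiff(cls, path: str | Path) -> "FeatureStack":
        grid, transform, crs, nodata, meta = read_geotiff(path)
        if grid.ndim == 2:
            grid = grid[None]
        names = meta.get("band_names", [f"f{i}" for i in range(grid.shape[0])])
        grids = {}
        for name, layer in zip(names, grid.astype(np.float64)):
            layer = layer.copy()
            if nodata is not None:
                layer[layer == nodata] = np.nan
            grids[name] = layer
        return cls(names=list(names), grids=grids,
                   mask_applied=bool(meta.get("mask_applied", False)),
                   transform=transform, crs=crs)


def compute_feature_stack(scene: SceneStack, registry: FeatureRegistry,
                          mask: WaterMask | None = None,
                          names: list[str] | None = None) -> FeatureStack:
    """Compute a set of registered features over a (optionally masked) scene."""
    names = names or registry.names()
    grids = {n: compute_feature(scene, registry[n], mask) for n in names}
    return FeatureStack(names=names, grids=grids, mask_applied=mask is not None,
                        transform=scene.transform, crs=scene.crs)
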