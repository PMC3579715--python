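"""Scenario configuration: YAML-backed, validated at load, fully serialisable.

A scenario file is the user interface for EMS design-change experiments: it
names the region source (generate synthetically, or load previously written
CSVs), the curve source, the static alarm-process intervals, the incidence
model, the resource sets to compare and the grid of static-interval shifts.
A run is reproducible from its config plus a seed alone; every defaulted
parameter is resolved at load and echoed into the run manifest, so nothing is
silently defaulted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass
from typing import Any

import yaml

from .curves import CurveParams
from .region import RegionConfig, RESOURCE_KINDS
from .survival import IncidenceModel, StaticIntervals, TAIL_31PLUS, TAIL_ZERO

DEFAULT_SHIFTS = (-2, -1, 0, 1, 2)
DEFAULT_RESOURCE_SETS = (("ambulance",), ("ambulance", "fire"))


class ConfigError(ValueError):
    """Raised for any invalid scenario configuration; message names the field."""


@dataclass(frozen=True)
class SourceSpec:
    """Where a region or curve set comes from: ``generate`` (from parameters,
    seeded) or ``load`` (from files previously written)."""

    source: str                      # "generate" | "load"
    path: str | None = None          # required for source == "load"


@dataclass(frozen=True)
class ScenarioConfig:
    region_source: SourceSpec
    curves_source: SourceSpec
    region: RegionConfig
    curve_params: CurveParams
    statics: StaticIntervals
    incidence: IncidenceModel
    resource_sets: tuple[tuple[str, ...], ...] = DEFAULT_RESOURCE_SETS
    shifts: tuple[int, ...] = DEFAULT_SHIFTS
    tail: str = TAIL_31PLUS

    def validate(self) -> None:
        for spec, what in ((self.region_source, "region"), (self.curves_source, "curves")):
            if spec.source not in ("generate", "load"):
                raise ConfigError(f"{what}.source must be 'generate' or 'load', got {spec.source!r}")
            if spec.source == "load" and not spec.path:
                raise ConfigError(f"{what}.path is required when {what}.source is 'load'")
        try:
            self.region.validate()
            self.curve_params.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if not self.resource_sets:
            raise ConfigError("resource_sets must name at least one resource set")
        for kinds in self.resource_sets:
            unknown = set(kinds) - set(RESOURCE_KINDS)
            if unknown:
                raise ConfigError(f"resource_sets: unknown kind(s) {sorted(unknown)}")
            if not kinds:
                raise ConfigError("resource_sets entries must be non-empty")
        if 0 not in self.shifts:
            raise ConfigError("shifts must include 0 (the baseline)")
        if self.tail not in (TAIL_31PLUS, TAIL_ZERO):
            raise ConfigError(f"tail must be '31plus' or 'zero', got {self.tail!r}")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "region": {"source": self.region_source.source,
                       "path": self.region_source.path,
                       "config": dataclasses.asdict(self.region)},
            "curves": {"source": self.curves_source.source,
                       "path": self.curves_source.path,
                       "params": dataclasses.asdict(self.curve_params)},
            "statics": dataclasses.asdict(self.statics),
            "incidence": dataclasses.asdict(self.incidence),
            "resource_sets": [list(k) for k in self.resource_sets],
            "shifts": list(self.shifts),
            "tail": self.tail,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ScenarioConfig":
        if not isinstance(raw, dict):
            raise ConfigError("scenario config must be a mapping")
        unknown = set(raw) - {"region", "curves", "statics", "incidence",
                              "resource_sets", "shifts", "tail"}
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

        def build(factory, section: dict, what: str):
            try:
                return factory(**section)
            except TypeError as exc:
                raise ConfigError(f"{what}: {exc}") from exc
            except ValueError as exc:
                raise ConfigError(f"{what}: {exc}") from exc

        region_raw = dict(raw.get("region") or {})
        curves_raw = dict(raw.get("curves") or {})
        region_cfg = dict(region_raw.pop("config", {}) or {})
        curve_par = dict(curves_raw.pop("params", {}) or {})
        for tup_key in ("fire_parttime_reaction_range", "locality_speeds_kmh",
                        "locality_speed_weights", "rural_speeds_kmh",
                        "rural_speed_weights"):
            if tup_key in region_cfg:
                region_cfg[tup_key] = tuple(region_cfg[tup_key])
        if "vf_early_bins" in curve_par:
            curve_par["vf_early_bins"] = tuple(curve_par["vf_early_bins"])

        cfg = cls(
            region_source=build(SourceSpec, {"source": region_raw.get("source", "generate"),
                                             "path": region_raw.get("path")}, "region"),
            curves_source=build(SourceSpec, {"source": curves_raw.get("source", "generate"),
                                             "path": curves_raw.get("path")}, "curves"),
            region=build(RegionConfig, region_cfg, "region.config"),
            curve_params=build(CurveParams, curve_par, "curves.params"),
            statics=build(StaticIntervals, dict(raw.get("statics") or {}), "statics"),
            incidence=build(IncidenceModel, dict(raw.get("incidence") or {}), "incidence"),
            resource_sets=tuple(tuple(k) for k in raw.get("resource_sets",
                                                          DEFAULT_RESOURCE_SETS)),
            shifts=tuple(int(v) for v in raw.get("shifts", DEFAULT_SHIFTS)),
            tail=raw.get("tail", TAIL_31PLUS),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "ScenarioConfig":
        try:
            raw = yaml.safe_load(pathlib.Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse YAML config: {exc}") from exc
        return cls.from_dict(raw or {})

    def write_yaml(self, path: str | pathlib.Path) -> pathlib.Path:
        path = pathlib.Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def default_config() -> ScenarioConfig:
    """Stockholm-like scenario with generated region and default curves."""
    cfg = ScenarioConfig(
        region_source=SourceSpec("generate"),
        curves_source=SourceSpec("generate"),
        region=RegionConfig(),
        curve_params=CurveParams(),
        statics=StaticIntervals(),
        incidence=IncidenceModel(),
    )
    cfg.validate()
    return cfg
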