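"""Run configuration: a single YAML document with per-stage sections.

Every seed is explicit and unknown keys are rejected by name, so a config file
fully determines a run and typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "STAGES"]

STAGES = ("seal", "telemetry", "forcing", "boxmodel", "section")


class ConfigError(ValueError):
    pass


@dataclass
class SealStage:
    n_seals: int = 72
    baseline_delta: float = 11.7
    slope_per_year: float = -0.036
    noise_sd: float = 0.66
    year_start: int = 1951
    year_end: int = 2012
    qc_tolerance: float = 1.0


@dataclass
class TelemetryStage:
    n_animals: int = 15
    n_fixes: int = 1500
    sigma_km: float = 300.0
    bandwidth_km: float = 250.0
    isopleth: float = 0.95


@dataclass
class ForcingStage:
    preindustrial_rate: float = 11.0
    modern_multiple: float = 2.5
    post1950_fraction: float = 0.60
    delta_dep: float = -4.0
    year_from: int = 1850
    year_to: int = 2019


@dataclass
class BoxmodelStage:
    year_from: int = 1850
    year_to: int = 2019
    window_from: int = 1970
    window_to: int = 2019


@dataclass
class SectionStage:
    n_years: int = 50
    n_depth: int = 10
    n_lat: int = 20
    u0: float = 0.10
    u_trend: float = 0.001
    area_trend: float = 0.02
    d15n_trend: float = -0.008


_STAGE_TYPES = {
    "seal": SealStage,
    "telemetry": TelemetryStage,
    "forcing": ForcingStage,
    "boxmodel": BoxmodelStage,
    "section": SectionStage,
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "isoscape_out"
    stages: tuple = STAGES
    seal: SealStage = field(default_factory=SealStage)
    telemetry: TelemetryStage = field(default_factory=TelemetryStage)
    forcing: ForcingStage = field(default_factory=ForcingStage)
    boxmodel: BoxmodelStage = field(default_factory=BoxmodelStage)
    section: SectionStage = field(default_factory=SectionStage)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        top_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = {}
        for name, stage_cls in _STAGE_TYPES.items():
            if name in data:
                sub = data.pop(name) or {}
                sub_fields = {f.name for f in dataclasses.fields(stage_cls)}
                bad = set(sub) - sub_fields
                if bad:
                    raise ConfigError(
                        f"unknown keys in section {name!r}: {sorted(bad)}"
                    )
                kwargs[name] = stage_cls(**sub)
        if "stages" in data:
            stages = tuple(data.pop("stages"))
            bad = set(stages) - set(STAGES)
            if bad:
                raise ConfigError(f"unknown stages requested: {sorted(bad)}")
            kwargs["stages"] = stages
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
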