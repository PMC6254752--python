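"""Pipeline configuration: strict YAML parsing with per-module defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError, ManifestError

__all__ = ["PipelineConfig", "RunSpec", "load_config"]


def _from_mapping(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {context!r}")
    return cls(**data)


@dataclass
class EcgConfig:
    threshold_fraction: float = 0.8
    refractory_ms: float = 200.0
    intensity_floor: float | None = None


@dataclass
class TracingConfig:
    near_roi: list | None = None
    far_roi: list | None = None
    near_threshold: float = 110.0
    far_threshold: float = 110.0
    doppler_threshold: float = 65.0
    doppler_start_column: int = 0
    exclusions: list = field(default_factory=list)
    smoothing_parameter: float = 0.001
    flow_side: str = "up"


@dataclass
class BeatsConfig:
    group_size: int = 6
    upstroke_r2: float = 0.985


@dataclass
class LoopConfig:
    dt_ms: float = 1.0
    fit_r2: float = 0.98


@dataclass
class EnsembleConfig:
    trim_fraction: float = 0.10
    per_tail: bool = False


@dataclass
class RunSpec:
    run_id: str
    kind: str  # "diameter" or "velocity"
    source: str  # "images" or "waveform"
    path: str
    r_peaks: str | None = None  # sidecar JSON for waveform sources

    def __post_init__(self) -> None:
        if self.kind not in ("diameter", "velocity"):
            raise ManifestError(f"run {self.run_id}: kind must be diameter or velocity")
        if self.source not in ("images", "waveform"):
            raise ManifestError(f"run {self.run_id}: source must be images or waveform")
        if self.source == "waveform" and not self.r_peaks:
            raise ManifestError(f"run {self.run_id}: waveform source needs an r_peaks sidecar")

    @property
    def modality(self) -> str:
        return "mmode" if self.kind == "diameter" else "doppler"


@dataclass
class PipelineConfig:
    runs: list[RunSpec] = field(default_factory=list)
    ecg: EcgConfig = field(default_factory=EcgConfig)
    tracing: TracingConfig = field(default_factory=TracingConfig)
    beats: BeatsConfig = field(default_factory=BeatsConfig)
    loop: LoopConfig = field(default_factory=LoopConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    output_dir: str = "out"
    base_dir: Path = field(default_factory=Path)  # resolved against config location

    def validate_manifest(self) -> None:
        kinds = {r.kind for r in self.runs}
        if "diameter" not in kinds or "velocity" not in kinds:
            raise ManifestError(
                "manifest must list at least one diameter and one velocity run"
            )
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            raise ManifestError("run_id values must be unique")


_SECTIONS = {
    "ecg": EcgConfig,
    "tracing": TracingConfig,
    "beats": BeatsConfig,
    "loop": LoopConfig,
    "ensemble": EnsembleConfig,
}


def config_from_dict(data: dict, base_dir: Path | str = ".") -> PipelineConfig:
    known = set(_SECTIONS) | {"runs", "output_dir"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg = PipelineConfig(base_dir=Path(base_dir))
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        setattr(cfg, name, _from_mapping(cls, section, name))
    cfg.output_dir = data.get("output_dir", "out")
    runs = data.get("runs", [])
    if not isinstance(runs, list):
        raise ConfigError("'runs' must be a list")
    cfg.runs = [_from_mapping(RunSpec, r, f"runs[{i}]") for i, r in enumerate(runs)]
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config_from_dict(data, base_dir=path.parent)
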