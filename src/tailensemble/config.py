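"""Run configuration: a YAML-serializable bundle of all stage parameters."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .alsd import ALSDConfig
from .energetics import ForceFieldParams
from .model_builder import ConfigurationError, ScaffoldSpec, ToySystemConfig
from .structanalysis import SASAParams


@dataclass(frozen=True)
class AnalysisParams:
    sasa_n_points: int = 240
    grid_spacing: float = 2.0
    contact_pad: float = 2.8
    burial_threshold: float = 0.1
    frame_stride: int = 1
    histogram_bins: int = 30

    def sasa_params(self) -> SASAParams:
        return SASAParams(n_sphere_points=self.sasa_n_points)


@dataclass(frozen=True)
class AdaptParams:
    n_iterations: int = 6
    steps_per_iteration: int = 8000
    flatness_threshold: float = 0.7
    ti_bootstrap: bool = True
    n_walkers: int = 4
    polish_rounds: int = 3
    polish_steps: int = 150000


@dataclass(frozen=True)
class RunConfig:
    system: ToySystemConfig = field(default_factory=ToySystemConfig)
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    sampler: ALSDConfig = field(default_factory=ALSDConfig)
    adapt: AdaptParams = field(default_factory=AdaptParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    acetylate_positions: tuple[int, ...] = ()  # 1-based tail positions
    n_runs: int = 8
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build(cls, data: dict, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(f"{context}: unknown fields {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; missing file section -> defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    sysdata = dict(raw.get("system", {}))
    if "scaffold_spec" in sysdata:
        sysdata["scaffold_spec"] = _build(ScaffoldSpec, dict(sysdata["scaffold_spec"]),
                                          "system.scaffold_spec")
    if "charge_pattern" in sysdata and sysdata["charge_pattern"] is not None:
        sysdata["charge_pattern"] = tuple(sysdata["charge_pattern"])
    return RunConfig(
        system=_build(ToySystemConfig, sysdata, "system"),
        forcefield=_build(ForceFieldParams, dict(raw.get("forcefield", {})), "forcefield"),
        sampler=_build(ALSDConfig, dict(raw.get("sampler", {})), "sampler"),
        adapt=_build(AdaptParams, dict(raw.get("adapt", {})), "adapt"),
        analysis=_build(AnalysisParams, dict(raw.get("analysis", {})), "analysis"),
        acetylate_positions=tuple(raw.get("acetylate_positions", ())),
        n_runs=int(raw.get("n_runs", 8)),
        seed=int(raw.get("seed", 0)),
    )


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
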