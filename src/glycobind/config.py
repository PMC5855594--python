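"""Run configuration: a validated, round-trippable description of one
simulate/fit pipeline run (model parameters, schedule, concentration
ladder, noise, fit options, paths). Unknown keys are rejected by name.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pydantic
import yaml

from .errors import ParseError
from .fitting import FitOptions
from .models import KineticParams, ModelKind, PhaseSchedule
from .synthetic import NoiseSpec

__all__ = ["RunConfig", "load_config", "save_config"]


class _Base(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class ScheduleConfig(_Base):
    t_assoc: float = 120.0
    t_dissoc: float = 600.0
    dt: float = 0.5

    def to_schedule(self) -> PhaseSchedule:
        return PhaseSchedule(self.t_assoc, self.t_dissoc, self.dt)


class LadderConfig(_Base):
    top_M: float = 250e-12
    factor: float = 2.0
    n: int = 5


class NoiseConfig(_Base):
    sd: float = 0.5
    drift: float = 0.0
    bulk: float = 0.0
    seed: int = 0

    def to_noise(self) -> NoiseSpec:
        return NoiseSpec(self.sd, self.drift, self.bulk, self.seed)


class ParamsConfig(_Base):
    kind: ModelKind = ModelKind.LANGMUIR_1TO1
    ka1: float = 5.9e6
    kd1: float = 8.5e-5
    rmax1: float = 100.0
    ka2: float | None = None
    kd2: float | None = None
    rmax2: float | None = None

    def to_params(self) -> KineticParams:
        return KineticParams(self.kind, self.ka1, self.kd1, self.rmax1,
                             self.ka2, self.kd2, self.rmax2)


class FitConfig(_Base):
    kind: ModelKind = ModelKind.LANGMUIR_1TO1
    n_starts: int = 8
    seed: int = 0
    include_offsets: bool = False

    def to_options(self) -> FitOptions:
        return FitOptions(n_starts=self.n_starts, seed=self.seed,
                          include_offsets=self.include_offsets)


class RunConfig(_Base):
    """Top-level pipeline configuration (YAML or JSON on disk)."""

    params: ParamsConfig = ParamsConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    ladder: LadderConfig = LadderConfig()
    noise: NoiseConfig = NoiseConfig()
    fit: FitConfig = FitConfig()
    input: str | None = None
    output: str | None = None

    def digest(self) -> str:
        """Stable hash of the configuration, for run logging."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON; unknown keys raise ParseError."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    try:
        return RunConfig.model_validate(data)
    except pydantic.ValidationError as exc:
        raise ParseError(f"invalid configuration {path}: {exc}") from exc


def save_config(path, config: RunConfig) -> None:
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix in (".json",):
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
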