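"""Run configurations: JSON files validated against a versioned schema.

Each CLI subcommand reads one of these models.  Validation happens before
any computation; a violation raises :class:`ConfigError` naming the field
path.  Every stochastic run carries an explicit seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import pydantic
from pydantic import BaseModel, Field

from .errors import ConfigError

SCHEMA_VERSION = 1


class GeometryConfig(BaseModel):
    gap: float = Field(gt=0, description="pillar gap, um")
    diagonal_major: float = Field(default=70.0, gt=0)
    diagonal_minor: float = Field(default=70.0, gt=0)
    height: float = Field(default=50.0, gt=0)
    fillet_radius: float = Field(default=2.0, ge=0)


class CellConfig(BaseModel):
    diameter: float = Field(gt=0, description="cell diameter, um")
    youngs_modulus: float = Field(gt=0, description="Pa")
    poisson_ratio: float = Field(default=0.3, gt=0, lt=0.5)


class ModelConfig(BaseModel):
    coefficient: float = Field(default=0.027, gt=0)
    exponent: float = Field(default=2.0, gt=0)


class LoadConfig(BaseModel):
    magnitude_pa: float = Field(ge=0)
    follower: bool = False


class SolverConfig(BaseModel):
    mesh_resolution: int = Field(default=4, ge=2)
    budget: int = Field(default=160, ge=1)
    tolerance_pa: float | None = Field(default=None, gt=0)
    seed: int = 0


class PredictConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    model: ModelConfig = ModelConfig()
    gap: float = Field(gt=0)
    cells: list[CellConfig] | None = None
    use_panel: bool = False  # evaluate the packaged cell panel instead


class SweepConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    diameters: list[float]
    moduli: list[float]
    gaps: list[float]
    geometry: GeometryConfig | None = None
    solver: SolverConfig = SolverConfig()


class SimulateConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    cell: CellConfig
    geometry: GeometryConfig
    load: LoadConfig
    solver: SolverConfig = SolverConfig()


class FlowConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    gap: float = Field(gt=0)
    flow_rate: float = Field(ge=0, description="uL/min")
    density: float = Field(default=1000.0, gt=0)
    viscosity: float = Field(default=1.0e-3, gt=0)
    channel_height: float = Field(default=50.0, gt=0)
    channel_width: float = Field(default=2000.0, gt=0)
    brinkman: bool = True


class CohortConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    n: int = Field(ge=1)
    mean: float = Field(default=17.27, gt=0)
    sd: float = Field(default=2.91, gt=0)
    seed: int = 0
    truncation: tuple[float, float] | None = None
    generator: Literal["normal", "binned"] = "normal"


class RouteConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    cohort: CohortConfig
    gaps: list[float] = [14.0, 10.0, 8.0, 4.0]
    rule: Literal["size-fraction", "critical-pressure"] = "size-fraction"
    threshold_fraction: float = Field(default=0.25, gt=0, lt=1)
    operating_pressure: float = Field(default=0.0, ge=0)
    model: ModelConfig = ModelConfig()


class CurvesConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    gaps: list[float] = [4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
    model: ModelConfig = ModelConfig()


class ValidateConfig(BaseModel):
    schema_version: int = SCHEMA_VERSION
    cell: CellConfig
    model: ModelConfig = ModelConfig()
    observations_csv: str  # columns gap_um, pc_pa


def load_config(path: str | Path, model_cls: type[BaseModel]) -> BaseModel:
    """Read and validate a JSON config; raise ConfigError naming the field."""
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        return model_cls.model_validate(raw)
    except pydantic.ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {locs}") from exc


def config_hash(cfg: BaseModel) -> str:
    """Short stable hash of a validated config, for output provenance."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
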