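"""Run configuration: a validated, round-trippable YAML schema.

Unknown keys are rejected and validation errors name the offending key.
CLI flags override file values.  An empty file yields all defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Raised when a configuration file is missing or invalid."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_StrictModel):
    grid_nx: int = Field(default=64, gt=0)
    grid_ny: int = Field(default=64, gt=0)
    n_angles: int = Field(default=60, gt=0)
    n_bins: int = Field(default=95, gt=0)
    pixel_size: float = Field(default=1.0, gt=0)
    bin_width: float = Field(default=1.0, gt=0)


class ProtocolConfig(_StrictModel):
    total_counts: float = Field(default=100_000.0, gt=0)
    random_fraction: float = Field(default=0.60, ge=0, le=1)
    scatter_fraction: float = Field(default=0.20, ge=0, le=1)
    n_realizations: int = Field(default=50, gt=0)
    matrix_error: float = Field(default=0.06, ge=0, le=0.15)


class EMConfig(_StrictModel):
    n_iter: int = Field(default=100, gt=0)


class PWLSConfig(_StrictModel):
    n_iter: int = Field(default=100, gt=0)
    beta: float | None = Field(default=None, ge=0)  # None -> scale-aware default


class UPWLSConfig(_StrictModel):
    alpha: float = Field(default=0.5, ge=0)
    assumed_error: float = Field(default=0.06, ge=0)
    qv: float = Field(default=0.0, ge=0)
    epsilon: float = Field(default=1e-4, gt=0)
    max_iter: int = Field(default=200, gt=0)
    lambda_mode: str = Field(default="alpha_shortcut", pattern="^(alpha_shortcut|line_search)$")
    x0_mode: str = Field(default="fbp", pattern="^(zero|fbp)$")


class RunConfig(_StrictModel):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    em: EMConfig = Field(default_factory=EMConfig)
    pwls: PWLSConfig = Field(default_factory=PWLSConfig)
    upwls: UPWLSConfig = Field(default_factory=UPWLSConfig)
    seed: int = 0
    log_level: str = "INFO"

    def scan_geometry(self):
        from .geometry import ScanGeometry

        g = self.geometry
        return ScanGeometry(
            grid_nx=g.grid_nx, grid_ny=g.grid_ny, n_angles=g.n_angles,
            n_bins=g.n_bins, pixel_size=g.pixel_size, bin_width=g.bin_width,
        )

    def scan_protocol(self):
        from .acquisition import ScanProtocol

        p = self.protocol
        return ScanProtocol(
            total_counts=p.total_counts, random_fraction=p.random_fraction,
            scatter_fraction=p.scatter_fraction, n_realizations=p.n_realizations,
            seed=self.seed,
        )


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        names = ", ".join(".".join(str(p) for p in err["loc"]) for err in exc.errors())
        raise ConfigError(f"invalid config ({names}): {exc}") from exc


def save_config(path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
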