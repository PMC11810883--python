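"""YAML run configuration with validated defaults.

Unset fields fall back to the method's standard design: sphere
``(h, r, d) = (0.5, 1.0, 0.3)``, ``k = 121`` projection centers, planar
grid 192, spherical grid 256.  Unknown keys are rejected so typos fail
loudly; the full resolved config is serialized into every output's
provenance record.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    h: float = 0.5
    r: float = 1.0
    d: float = 0.3
    spherical_grid_size: int = 256
    planar_grid_size: int = 192
    interpolation_order: int = 1
    fill_value: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "GeometryConfig":
        if min(self.h, self.r, self.d) <= 0:
            raise ValueError("h, r, d must be positive")
        if self.d >= self.r:
            raise ValueError("d must be smaller than r")
        return self


class CenterGridConfig(_Strict):
    count: int = 121
    extent_fraction: float = 0.5


class PredictorConfig(_Strict):
    depth: int = 3
    base_channels: int = 16
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 3e-3
    seed: int = 0


class UqConfig(_Strict):
    value_bins: int = 2
    otsu_bins: int = 256


class ScoringConfig(_Strict):
    pixel_spacing_mm: float = 1.0


class RunConfig(_Strict):
    geometry: GeometryConfig = GeometryConfig()
    center_grid: CenterGridConfig = CenterGridConfig()
    predictor: PredictorConfig = PredictorConfig()
    uq: UqConfig = UqConfig()
    scoring: ScoringConfig = ScoringConfig()
    seed: int = 0
    log_level: str = "INFO"

    def to_geometry(self):
        from .geometry import ProjectionGeometry

        return ProjectionGeometry(
            plane_half_width=self.geometry.h,
            sphere_radius=self.geometry.r,
            plane_distance=self.geometry.d,
            spherical_grid_size=self.geometry.spherical_grid_size,
            planar_grid_size=self.geometry.planar_grid_size,
            interpolation_order=self.geometry.interpolation_order,
            fill_value=self.geometry.fill_value,
        )

    def provenance(self) -> dict[str, Any]:
        import sphereseg

        return {"config": self.model_dump(), "version": sphereseg.__version__}


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` or an empty file yields the
    full defaults.  Schema violations raise :class:`ConfigError` listing the
    offending keys."""
    data: Any = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        keys = ", ".join(
            "->".join(str(p) for p in e["loc"]) or "<root>" for e in err.errors()
        )
        raise ConfigError(f"invalid config keys or values: {keys}") from err


def write_provenance(path: str | Path, config: RunConfig, **extra: Any) -> None:
    record = config.provenance() | extra
    Path(path).write_text(json.dumps(record, indent=2, default=str))
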