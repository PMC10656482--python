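"""Run configuration: validated YAML → pydantic models.

Unknown keys are rejected everywhere (``extra="forbid"``) so typos fail
before any stage runs.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError
from .types import CLASS_CODES, DEFAULT_GRADING


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThermalConfig(_Strict):
    """Thermal-band calibration: radiance = gain·DN + bias; K1/K2 Planck constants."""

    gain: float = 0.055376
    bias: float = 1.18243
    k1: float = 607.76
    k2: float = 1260.56


class AtmosphereConfig(_Strict):
    """Atmospheric terms for the single-channel temperature inversion."""

    l_up: float = 0.0
    l_down: float = 0.0
    tau: float = 1.0
    emissivity: float = 1.0
    emissivity_mode: Literal["constant", "ndvi_threshold"] = "constant"


class EpochConfig(_Strict):
    year: int | str
    scene: str
    landuse: Optional[str] = None
    sensor: str = "TM"


class RunConfig(_Strict):
    """Full end-to-end run: epochs, physics constants, analysis options."""

    epochs: list[EpochConfig] = Field(min_length=1)
    thermal: ThermalConfig = ThermalConfig()
    atmosphere: AtmosphereConfig = AtmosphereConfig()
    grading: Optional[dict[str, int]] = None
    epsilon: float = 0.05           # no-change half-width for change maps
    water_mask: bool = True         # drop water cells before normalize/PCA
    pc1_transform: Literal["orient_ndvi", "one_minus"] = "orient_ndvi"
    clip_percentiles: Optional[tuple[float, float]] = None
    kelvin_offset: float = 273.0
    out_dir: str = "rseikit_out"
    seed: int = 0

    @field_validator("grading")
    @classmethod
    def _known_classes(cls, v):
        if v is not None:
            unknown = set(v) - set(CLASS_CODES)
            if unknown:
                raise ValueError(f"unknown land-use classes in grading: {sorted(unknown)}")
        return v

    def grading_by_code(self) -> dict[int, int]:
        if self.grading is None:
            return dict(DEFAULT_GRADING)
        return {CLASS_CODES[name]: grade for name, grade in self.grading.items()}


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a YAML mapping")
    try:
        return RunConfig(**raw)
    except Exception as exc:  # pydantic ValidationError → domain error
        raise ConfigurationError(f"{path}: {exc}") from exc
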