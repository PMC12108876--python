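"""Run configuration: schema-validated parameters for the full pipeline.

Defaults reproduce the bundled reference patient: 65 kg body mass,
EI = 15.1 N·m², 42 mm of spine below the curve, axial load 40% and
lateral load 25% of body weight, traction along the spine axis, g = 10.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["PatientConfig", "LoadConfig", "PlanningConfig", "NumericsConfig", "RunConfig"]


class PatientConfig(BaseModel):
    mass_kg: float = Field(65.0, gt=0)
    EI_Nm2: float = Field(15.1, gt=0)
    Li_mm: float = Field(42.0, ge=0)


class LoadConfig(BaseModel):
    axial_fraction: float = Field(0.40, ge=0, le=1)
    lateral_fraction: float = Field(0.25, ge=0, le=1)
    alpha_deg: float = Field(0.0, ge=0, lt=90)
    g: float = Field(10.0, gt=0)


class PlanningConfig(BaseModel):
    station_m: float = 0.095
    target_m: float = 0.0
    bracket_N: tuple[float, float] = (1.0, 1.0e6)

    @field_validator("bracket_N")
    @classmethod
    def _ordered(cls, v):
        if v[0] <= 0 or v[1] <= v[0]:
            raise ValueError("bracket must satisfy 0 < lo < hi")
        return v


class NumericsConfig(BaseModel):
    n_nodes: int = Field(2001, ge=201)
    root_tol_N: float = Field(0.5, gt=0)
    numeric_cross_check: bool = False

    @field_validator("n_nodes")
    @classmethod
    def _odd(cls, v):
        if v % 2 == 0:
            raise ValueError("n_nodes must be odd")
        return v


class RunConfig(BaseModel):
    """Full pipeline configuration; loadable from YAML or JSON."""

    input_csv: str | None = None  # None -> bundled reference midline
    patient: PatientConfig = PatientConfig()
    loads: LoadConfig = LoadConfig()
    planning: PlanningConfig = PlanningConfig()
    numerics: NumericsConfig = NumericsConfig()
    tradeoff_Q_points: int = Field(5, ge=1)
    output_json: str | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data)

    def to_file(self, path) -> None:
        path = Path(path)
        data = self.model_dump()
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
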