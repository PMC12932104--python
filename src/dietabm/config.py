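"""Run configuration: schema-validated YAML in, resolved defaults out.

A run is fully determined by (config, master seed).  Unknown keys are
rejected so typos cannot silently fall back to defaults.
"""
from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import calibration, environment

__all__ = ["RunConfig", "EnvironmentSpec", "SimulationSpec", "load_config"]

_TREATMENT_NAMES = ("exposure_enhancement_peering", "exposure_enhancement", "exposure_only")


class EnvironmentSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_items: int = Field(environment.DEFAULT_N_ITEMS, ge=1)
    daily_patch_mean: float = Field(environment.DEFAULT_PATCH_MEAN, gt=0)
    tail_exponent: float = Field(environment.DEFAULT_TAIL_EXPONENT, ge=0)
    complexity_mix: tuple[float, float, float, float, float, float] = (
        environment.DEFAULT_COMPLEXITY_MIX
    )
    csv_path: str | None = None
    build_seed: int = environment._DEFAULT_ENV_SEED

    def build(self) -> environment.Environment:
        if self.csv_path is not None:
            return environment.load_food_table(
                self.csv_path, daily_patch_mean=self.daily_patch_mean
            )
        import numpy as np

        return environment.build_default_environment(
            n_items=self.n_items,
            tail_exponent=self.tail_exponent,
            complexity_mix=self.complexity_mix,
            rng=np.random.default_rng(self.build_seed),
            daily_patch_mean=self.daily_patch_mean,
        )


class SimulationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    years: int = Field(15, ge=1)
    days_per_year: int = Field(365, ge=1)
    independence_age: int = Field(9, ge=0)
    cohort_size: int = Field(250, ge=1)

    @field_validator("independence_age")
    @classmethod
    def _indep_in_span(cls, v, info):
        years = info.data.get("years", 15)
        if v >= years:
            raise ValueError("independence_age must be < years")
        return v

    def build(self, seed: int | None = None):
        from .simulator import SimulationConfig

        return SimulationConfig(
            years=self.years,
            days_per_year=self.days_per_year,
            independence_age=self.independence_age,
            cohort_size=self.cohort_size,
            seed=seed,
        )


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    environment: EnvironmentSpec = EnvironmentSpec()
    calibration: dict[str, float | bool] | None = None
    treatments: list[str] = list(_TREATMENT_NAMES)
    simulation: SimulationSpec = SimulationSpec()
    output_dir: str = "results"

    @field_validator("treatments")
    @classmethod
    def _known_treatments(cls, v):
        unknown = [t for t in v if t not in _TREATMENT_NAMES]
        if unknown:
            raise ValueError(
                f"unknown treatments {unknown}; choose from {_TREATMENT_NAMES}"
            )
        return v

    def build_calibration(self) -> calibration.CalibrationSet:
        if self.calibration is None:
            return calibration.default_calibration()
        return calibration.CalibrationSet.from_dict(self.calibration)

    def resolved_yaml(self) -> str:
        data = self.model_dump()
        if data["calibration"] is None:
            data["calibration"] = self.build_calibration().to_dict()
        data["environment"]["complexity_mix"] = list(
            data["environment"]["complexity_mix"]
        )
        return yaml.safe_dump(data, sort_keys=True)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Omitted optional fields are filled with package defaults; schema
    violations raise with the offending key path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.model_validate(raw)
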